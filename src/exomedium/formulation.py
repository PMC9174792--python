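"""Defined-medium formulation: elemental stoichiometry, C:N ratios, recipes.

A defined medium is modelled as a list of metabolite components, each with a
molecular formula, a concentration tier ("group") and a molar concentration,
plus an inorganic salt profile and pass-through supplement lines (vitamin and
trace-mineral mixes whose exact composition is not tracked elementally).

Groups are *concentration tiers*, not strict chemical classes: the medium
design assigns every member of a tier the same molar concentration, which is
what makes the closed-form carbon-budget solver below possible. Organic C and
N are accounted per component as ``atom count x atomic weight x µM x 1e-3``
(mg/L); inorganic N from the salt profile (e.g. ammonium) is tracked
separately and can optionally enter the C:N denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import ATOMIC_WEIGHTS, ATOMIC_WEIGHT_VERSION, ElementTally, molar_mass, parse_formula

GROUPS = ("sugars", "organic_acids", "amino_acids", "other")

#: Salt entries whose formula unit carries one nitrogen atom.
DEFAULT_INORGANIC_N = frozenset({"ammonium", "ammonia", "nitrate", "nitrite"})

COMPONENT_SOURCES = ("main_text", "tier_inferred", "inferred")


class MediumFormatError(ValueError):
    """A medium definition file violates the schema."""


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class MediumComponent:
    """One metabolite line of a defined medium."""

    name: str
    formula: ElementTally
    group: str
    conc_uM: float
    source: str = "main_text"

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not (math.isfinite(self.conc_uM) and self.conc_uM > 0):
            raise ValueError(f"concentration must be finite and > 0, got {self.conc_uM}")
        if self.source not in COMPONENT_SOURCES:
            raise ValueError(f"unknown provenance flag {self.source!r}")


@dataclass(frozen=True)
class SaltProfile:
    """Inorganic ion/element concentrations in mM.

    ``inorganic_n`` names the entries whose formula unit contributes one
    nitrogen atom (ammonium, nitrate, ...); their N mass can be folded into
    C:N ratios on request.
    """

    mM: Mapping[str, float] = field(default_factory=dict)
    inorganic_n: frozenset = DEFAULT_INORGANIC_N

    def __post_init__(self):
        for ion, c in self.mM.items():
            if not (math.isfinite(c) and c >= 0):
                raise ValueError(f"salt {ion!r} concentration must be >= 0, got {c}")
        object.__setattr__(self, "mM", dict(self.mM))
        object.__setattr__(self, "inorganic_n", frozenset(self.inorganic_n))

    def inorganic_n_mg_per_l(self) -> float:
        """N mass (mg/L) contributed by flagged salt entries (1 N per unit)."""
        return sum(
            c * ATOMIC_WEIGHTS["N"] for ion, c in self.mM.items() if ion in self.inorganic_n
        )


@dataclass(frozen=True)
class MediumDefinition:
    """A complete defined medium: components, salts, supplements, pH range."""

    name: str
    components: tuple[MediumComponent, ...]
    salts: SaltProfile = field(default_factory=SaltProfile)
    supplements: tuple[tuple[str, float], ...] = ()
    ph_range: tuple[float, float] = (7.0, 7.2)

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(
            self, "supplements", tuple((str(n), float(f)) for n, f in self.supplements)
        )
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate component names: {dupes}")
        lo, hi = self.ph_range
        if not lo <= hi:
            raise ValueError(f"pH range must be (low, high), got {self.ph_range}")

    def group(self, group: str) -> tuple[MediumComponent, ...]:
        return tuple(c for c in self.components if c.group == group)

    def scaled(self, factor: float) -> "MediumDefinition":
        """Uniformly scale every component concentration (salts untouched)."""
        if not factor > 0:
            raise ValueError("scale factor must be > 0")
        return MediumDefinition(
            name=self.name,
            components=tuple(
                MediumComponent(c.name, c.formula, c.group, c.conc_uM * factor, c.source)
                for c in self.components
            ),
            salts=self.salts,
            supplements=self.supplements,
            ph_range=self.ph_range,
        )


def element_mass_concentration(component: MediumComponent, element: str) -> float:
    """Mass concentration (mg/L) of *element* contributed by one component.

    ``count x atomic weight (g/mol) x µM x 1e-3``; zero when the element is
    absent from the component's formula.
    """
    n = component.formula.count(element)
    if n == 0:
        return 0.0
    return n * ATOMIC_WEIGHTS[element] * component.conc_uM * 1e-3


def total_element_mass(medium: MediumDefinition, element: str) -> float:
    """Total organic mass concentration (mg/L) of *element* over all components."""
    return sum(element_mass_concentration(c, element) for c in medium.components)


def stoichiometry_table(medium: MediumDefinition, rounded: bool = False) -> pd.DataFrame:
    """Per-tier organic C and N budget, with a totals row.

    Returns a DataFrame indexed by group (plus ``total``) with columns
    ``uM_each`` (the tier concentration; NaN if members are not equimolar),
    ``n_compounds``, ``C_mg_L`` and ``N_mg_L``. With ``rounded=True`` the
    mg/L columns are rounded half-away-from-zero to integers (the display
    convention); the totals row is rounded from the full-precision total,
    not from the rounded group rows.
    """
    rows = {}
    for g in GROUPS:
        comps = medium.group(g)
        concs = {c.conc_uM for c in comps}
        rows[g] = {
            "uM_each": concs.pop() if len(concs) == 1 else float("nan"),
            "n_compounds": len(comps),
            "C_mg_L": sum(element_mass_concentration(c, "C") for c in comps),
            "N_mg_L": sum(element_mass_concentration(c, "N") for c in comps),
        }
    rows["total"] = {
        "uM_each": float("nan"),
        "n_compounds": len(medium.components),
        "C_mg_L": sum(r["C_mg_L"] for g, r in rows.items()),
        "N_mg_L": sum(r["N_mg_L"] for g, r in rows.items()),
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    df["n_compounds"] = df["n_compounds"].astype(int)
    if rounded:
        for col in ("C_mg_L", "N_mg_L"):
            df[col] = [_round_half_away(v) for v in df[col]]
    return df


def cn_ratio(
    medium: MediumDefinition,
    basis: str = "molar",
    include_inorganic_n: bool = False,
) -> float:
    """Carbon-to-nitrogen ratio of the medium.

    ``basis='molar'`` divides mole concentrations (mass / atomic weight);
    ``basis='mass'`` divides mg/L directly. With ``include_inorganic_n`` the
    N from flagged salt entries (ammonium etc.) enters the denominator.
    """
    if basis not in ("molar", "mass"):
        raise ValueError(f"basis must be 'molar' or 'mass', got {basis!r}")
    c = total_element_mass(medium, "C")
    n = total_element_mass(medium, "N")
    if include_inorganic_n:
        n += medium.salts.inorganic_n_mg_per_l()
    if n <= 0:
        raise ZeroDivisionError("medium contains no nitrogen under the chosen options")
    if basis == "molar":
        return (c / ATOMIC_WEIGHTS["C"]) / (n / ATOMIC_WEIGHTS["N"])
    return c / n


def solve_tier_scale(
    components: Sequence[tuple[ElementTally, float]], target_c_mg_l: float
) -> float:
    """Base concentration (µM) so tiered components hit a carbon budget.

    Components are (formula, tier multiplier) pairs; component *i* is dosed
    at ``base x mult_i`` µM. Total C is linear in the base, so the solve is
    closed-form: ``base = target / sum(mult_i x nC_i x 12.011 x 1e-3)``.
    """
    if not target_c_mg_l > 0:
        raise ValueError("target carbon must be > 0")
    coeff = 0.0
    for tally, mult in components:
        if not mult > 0:
            raise ValueError("tier multipliers must be > 0")
        coeff += mult * tally.count("C") * ATOMIC_WEIGHTS["C"] * 1e-3
    if coeff == 0.0:
        raise ValueError("no carbon in any component; carbon budget unsolvable")
    return target_c_mg_l / coeff


def solve_cn_scale(
    medium: MediumDefinition, target_ratio: float, basis: str = "molar"
) -> float:
    """Uniform component scale factor achieving a target C:N ratio.

    The organic C:N is scale-invariant, so a finite solution exists only when
    inorganic N (e.g. the ammonium in the salt profile) anchors the
    denominator: scaling components by *s* changes the ratio through
    ``s*C / (s*N_org + N_inorg)``.
    """
    if basis not in ("molar", "mass"):
        raise ValueError(f"basis must be 'molar' or 'mass', got {basis!r}")
    c = total_element_mass(medium, "C")
    n_org = total_element_mass(medium, "N")
    n_inorg = medium.salts.inorganic_n_mg_per_l()
    if basis == "molar":
        c /= ATOMIC_WEIGHTS["C"]
        n_org /= ATOMIC_WEIGHTS["N"]
        n_inorg /= ATOMIC_WEIGHTS["N"]
    if n_inorg <= 0:
        raise ValueError(
            "organic C:N is invariant under uniform scaling; an inorganic N "
            "anchor (e.g. ammonium) is required to solve for a target ratio"
        )
    denom = c - target_ratio * n_org
    if denom <= 0:
        raise ValueError(
            f"target C:N {target_ratio} is not reachable: it meets or exceeds "
            f"the organic-only ratio {c / n_org:.3f}, the supremum under scaling"
        )
    s = target_ratio * n_inorg / denom
    return s


def recipe(medium: MediumDefinition) -> pd.DataFrame:
    """Weigh-out table: one row per metabolite (mg/L = µM x M x 1e-3), plus
    salt and supplement pass-through lines."""
    rows = []
    for c in medium.components:
        rows.append(
            {
                "kind": "metabolite",
                "name": c.name,
                "group": c.group,
                "conc_uM": c.conc_uM,
                "mg_L": c.conc_uM * molar_mass(c.formula) * 1e-3,
            }
        )
    for ion, mm in medium.salts.mM.items():
        rows.append({"kind": "salt", "name": ion, "group": "", "conc_uM": mm * 1000.0, "mg_L": float("nan")})
    for name, fold in medium.supplements:
        rows.append({"kind": "supplement", "name": name, "group": "", "conc_uM": float("nan"), "mg_L": fold})
    return pd.DataFrame(rows, columns=["kind", "name", "group", "conc_uM", "mg_L"])


# ---------------------------------------------------------------------------
# serialization

_TSV_COLUMNS = [
    "kind", "name", "formula", "group", "conc_uM", "mM", "fold",
    "source", "inorganic_n", "ph_low", "ph_high",
]


def medium_to_dict(medium: MediumDefinition) -> dict:
    return {
        "name": medium.name,
        "ph": list(medium.ph_range),
        "components": [
            {
                "name": c.name,
                "formula": c.formula.hill(),
                "group": c.group,
                "conc_uM": c.conc_uM,
                "source": c.source,
            }
            for c in medium.components
        ],
        "salts": dict(medium.salts.mM),
        "salts_inorganic_n": sorted(medium.salts.inorganic_n & set(medium.salts.mM)),
        "supplements": [{"name": n, "fold": f} for n, f in medium.supplements],
    }


def medium_from_dict(d: Mapping) -> MediumDefinition:
    try:
        components = []
        seen = set()
        for i, row in enumerate(d.get("components", []), start=1):
            name = row["name"]
            if name in seen:
                raise MediumFormatError(f"component {i} ({name!r}): duplicate name")
            seen.add(name)
            if row["group"] not in GROUPS:
                raise MediumFormatError(
                    f"component {i} ({name!r}): unknown group {row['group']!r}"
                )
            try:
                tally = parse_formula(row["formula"])
            except ValueError as e:
                raise MediumFormatError(f"component {i} ({name!r}): {e}") from e
            components.append(
                MediumComponent(
                    name=name,
                    formula=tally,
                    group=row["group"],
                    conc_uM=float(row["conc_uM"]),
                    source=row.get("source", "main_text"),
                )
            )
        salts = SaltProfile(
            mM={k: float(v) for k, v in d.get("salts", {}).items()},
            inorganic_n=frozenset(d.get("salts_inorganic_n", DEFAULT_INORGANIC_N)),
        )
        supplements = tuple((s["name"], float(s["fold"])) for s in d.get("supplements", []))
        ph = d.get("ph", [7.0, 7.2])
        return MediumDefinition(
            name=d.get("name", "medium"),
            components=tuple(components),
            salts=salts,
            supplements=supplements,
            ph_range=(float(ph[0]), float(ph[1])),
        )
    except (KeyError, TypeError) as e:
        raise MediumFormatError(f"malformed medium definition: {e}") from e


def _infer_dialect(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "tsv" if str(path).endswith((".tsv", ".txt")) else "json"


def write_medium(medium: MediumDefinition, path, dialect: str | None = None) -> None:
    """Serialize a medium definition to JSON or TSV (see module docs)."""
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(medium_to_dict(medium), fh, indent=2)
            fh.write("\n")
        return
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = [
        {
            "kind": "medium", "name": medium.name,
            "ph_low": medium.ph_range[0], "ph_high": medium.ph_range[1],
        }
    ]
    for c in medium.components:
        rows.append(
            {
                "kind": "component", "name": c.name, "formula": c.formula.hill(),
                "group": c.group, "conc_uM": c.conc_uM, "source": c.source,
            }
        )
    for ion, mm in medium.salts.mM.items():
        rows.append(
            {
                "kind": "salt", "name": ion, "mM": mm,
                "inorganic_n": int(ion in medium.salts.inorganic_n),
            }
        )
    for name, fold in medium.supplements:
        rows.append({"kind": "supplement", "name": name, "fold": fold})
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_medium(path, dialect: str | None = None) -> MediumDefinition:
    """Read a medium definition written by :func:`write_medium`.

    Schema violations (duplicate names, unknown group labels, unparsable
    formulas) are reported with the offending row.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as e:
                raise MediumFormatError(f"{path}: invalid JSON: {e}") from e
        return medium_from_dict(d)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "kind" not in df.columns:
        raise MediumFormatError(f"{path}: missing mandatory header with 'kind' column")
    name, ph = "medium", (7.0, 7.2)
    components: list[MediumComponent] = []
    seen: set[str] = set()
    salts: dict[str, float] = {}
    inorganic: set[str] = set()
    supplements: list[tuple[str, float]] = []
    for idx, row in df.iterrows():
        rowno = int(idx) + 2  # 1-based, after the header line
        kind = row["kind"]
        try:
            if kind == "medium":
                name = row["name"]
                ph = (float(row["ph_low"]), float(row["ph_high"]))
            elif kind == "component":
                if row["name"] in seen:
                    raise MediumFormatError(f"duplicate component name {row['name']!r}")
                seen.add(row["name"])
                if row["group"] not in GROUPS:
                    raise MediumFormatError(f"unknown group {row['group']!r}")
                components.append(
                    MediumComponent(
                        name=row["name"],
                        formula=parse_formula(row["formula"]),
                        group=row["group"],
                        conc_uM=float(row["conc_uM"]),
                        source=row["source"] or "main_text",
                    )
                )
            elif kind == "salt":
                salts[row["name"]] = float(row["mM"])
                flag = str(row.get("inorganic_n", "")).strip().lower()
                if flag not in ("", "0", "0.0", "false"):
                    inorganic.add(row["name"])
            elif kind == "supplement":
                supplements.append((row["name"], float(row["fold"])))
            else:
                raise MediumFormatError(f"unknown record kind {kind!r}")
        except MediumFormatError as e:
            raise MediumFormatError(f"{path}: row {rowno}: {e}") from None
        except ValueError as e:
            raise MediumFormatError(f"{path}: row {rowno}: {e}") from None
    return MediumDefinition(
        name=name,
        components=tuple(components),
        salts=SaltProfile(mM=salts, inorganic_n=frozenset(inorganic)),
        supplements=tuple(supplements),
        ph_range=ph,
    )


def write_stoichiometry_report(medium: MediumDefinition, path, rounded: bool = True) -> None:
    """Write the per-tier C/N budget as TSV with an atomic-weight header line."""
    df = stoichiometry_table(medium, rounded=rounded)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# atomic weights: {ATOMIC_WEIGHT_VERSION}\n")
        df.to_csv(fh, sep="\t")
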