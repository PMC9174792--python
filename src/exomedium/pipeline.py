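"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` chains the profiling stages (blank subtraction, optional
blank-ratio filter, normalization, fold changes, rank-sum utilization
calls, Bray-Curtis clustering) and, when a tree is supplied, the
conservatism analyses (patristic distances, Euclidean profile distances,
seeded Mantel association, within-group similarity test). Every output file
is declared in a ``manifest.json`` recording input hashes, parameters and
package versions — no timestamps, so a rerun with the same inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

from . import __version__
from .chem import ATOMIC_WEIGHT_VERSION
from .conservatism import (
    distance_association,
    group_conservatism_test,
    patristic_distances,
    profile_distances,
    read_groups,
    read_tree,
)
from .exoprofile import (
    blank_ratio_filter,
    blank_subtract,
    cluster_profiles,
    count_significant,
    depletion_test,
    fold_change,
    isolate_mean_profiles,
    normalize,
    read_peak_table,
    write_calls,
)
from .growth import analyze_plate, read_growth_csv, read_plate_map


class DataError(ValueError):
    """Input data failed to parse or violated a schema."""


@dataclasses.dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    peaks: str | None = None
    samples: str | None = None
    tree: str | None = None
    groups: str | None = None
    growth: str | None = None
    plate_map: str | None = None
    alpha: float = 0.05
    blank_ratio: float | None = 10.0
    growth_threshold: float = 0.05
    linkage: str = "average"
    n_perm: int = 999
    seed: int = 0


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage the config provides inputs for; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path_fields = ("peaks", "samples", "tree", "groups", "growth", "plate_map")
    inputs = {
        name: path
        for name, path in dataclasses.asdict(config).items()
        if name in path_fields and path is not None
    }
    for name, path in inputs.items():
        if not Path(path).is_file():
            raise DataError(f"input {name!r} not found: {path}")
    manifest: dict = {
        "versions": {"exomedium": __version__, "atomic_weights": ATOMIC_WEIGHT_VERSION},
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k not in inputs
        },
        "inputs": {name: {"path": path, "sha256": _sha256(path)} for name, path in inputs.items()},
        "outputs": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)

    fc = None
    if config.peaks and config.samples:
        try:
            table = read_peak_table(config.peaks, config.samples)
        except ValueError as e:
            raise DataError(str(e)) from e
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = blank_subtract(table)
            if config.blank_ratio:
                table = blank_ratio_filter(table, ratio=config.blank_ratio)
        norm = normalize(table)
        fc = fold_change(norm)
        calls = depletion_test(norm, alpha=config.alpha)
        means = isolate_mean_profiles(norm)
        clust = cluster_profiles(means, method=config.linkage)
        emit("normalized.tsv", lambda p: norm.data.rename_axis("metabolite").to_csv(p, sep="\t"))
        emit("fold_changes.tsv", lambda p: fc.log2.rename_axis("metabolite").to_csv(p, sep="\t"))
        emit("calls.tsv", lambda p: write_calls(calls, fc, p))
        emit(
            "depleted_counts.tsv",
            lambda p: count_significant(calls).rename("n_depleted").rename_axis("isolate").to_csv(p, sep="\t"),
        )
        emit("braycurtis.tsv", lambda p: clust.distance.rename_axis("isolate").to_csv(p, sep="\t"))
        emit("dendrogram.nwk", lambda p: Path(p).write_text(clust.newick + "\n"))

    if config.tree and fc is not None:
        try:
            tree = read_tree(config.tree)
            phylo = patristic_distances(tree)
        except ValueError as e:
            raise DataError(str(e)) from e
        shared = [i for i in fc.isolates if i in phylo.index]
        if len(shared) < 4:
            raise DataError(
                f"only {len(shared)} isolates shared between tree and peak table; need >= 4"
            )
        phylo = phylo.loc[shared, shared]
        prof = profile_distances(fc).loc[shared, shared]
        assoc = distance_association(phylo, prof, n_perm=config.n_perm, seed=config.seed)
        emit("phylo_distances.tsv", lambda p: phylo.rename_axis("isolate").to_csv(p, sep="\t"))
        emit("profile_distances.tsv", lambda p: prof.rename_axis("isolate").to_csv(p, sep="\t"))
        report = dataclasses.asdict(assoc)
        if config.groups:
            groups = read_groups(config.groups)
            try:
                g = group_conservatism_test(fc, groups)
                report["group_test"] = dataclasses.asdict(g)
            except ValueError as e:
                report["group_test"] = {"error": str(e)}
        emit(
            "association.json",
            lambda p: Path(p).write_text(json.dumps(report, indent=2) + "\n"),
        )

    if config.growth and config.plate_map:
        try:
            plate = read_growth_csv(config.growth)
            plate_map = read_plate_map(config.plate_map)
        except ValueError as e:
            raise DataError(str(e)) from e
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = analyze_plate(plate, plate_map, threshold=config.growth_threshold)
        emit("growth_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))

    if not manifest["outputs"]:
        raise DataError("configuration provides no runnable stage inputs")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
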