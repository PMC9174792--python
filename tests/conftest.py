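import numpy as np
import pandas as pd
import pytest

from exomedium import load_fixture
from exomedium.exoprofile import ROLE_BLANK, ROLE_CONTROL, PeakTable

#: free amino acids at the tier concentration used for the stoichiometry checks
AMINO_ACID_FORMULAS = {
    "glycine": "C2H5NO2", "alanine": "C3H7NO2", "serine": "C3H7NO3",
    "proline": "C5H9NO2", "valine": "C5H11NO2", "threonine": "C4H9NO3",
    "cysteine": "C3H7NO2S", "leucine": "C6H13NO2", "isoleucine": "C6H13NO2",
    "asparagine": "C4H8N2O3", "aspartic acid": "C4H7NO4", "glutamine": "C5H10N2O3",
    "lysine": "C6H14N2O2", "glutamic acid": "C5H9NO4", "methionine": "C5H11NO2S",
    "histidine": "C6H9N3O2", "phenylalanine": "C9H11NO2", "arginine": "C6H14N4O2",
    "tyrosine": "C9H11NO3", "tryptophan": "C11H12N2O2",
}


@pytest.fixture(scope="session")
def nldm():
    return load_fixture("nldm_medium")


@pytest.fixture(scope="session")
def toy_peaks():
    return load_fixture("toy_peaks")


@pytest.fixture(scope="session")
def toy_tree():
    return load_fixture("toy_tree")


def make_peak_table(
    values: dict[str, dict[str, list[float]]],
    n_controls: int = 3,
    control_values: dict[str, list[float]] | None = None,
    blank_values: dict[str, list[float]] | None = None,
) -> PeakTable:
    """Assemble a PeakTable from per-metabolite replicate lists.

    ``values[metabolite][isolate] -> replicate list``; control and blank
    values are per-metabolite lists.
    """
    metabolites = list(values)
    columns: dict[str, list[float]] = {}
    ann = []
    isolates = sorted({iso for per_met in values.values() for iso in per_met})
    for iso in isolates:
        n_rep = len(next(iter(values.values()))[iso])
        for r in range(n_rep):
            sid = f"{iso}_r{r + 1}"
            columns[sid] = [values[m][iso][r] for m in metabolites]
            ann.append({"sample_id": sid, "role": "culture", "isolate": iso, "replicate": r + 1})
    if control_values is not None:
        n_controls = len(next(iter(control_values.values())))
    for r in range(n_controls):
        sid = f"ctrl_r{r + 1}"
        if control_values is not None:
            columns[sid] = [control_values[m][r] for m in metabolites]
        else:
            columns[sid] = [100.0] * len(metabolites)
        ann.append({"sample_id": sid, "role": ROLE_CONTROL, "isolate": "", "replicate": r + 1})
    if blank_values is not None:
        for r in range(len(next(iter(blank_values.values())))):
            sid = f"blank_r{r + 1}"
            columns[sid] = [blank_values[m][r] for m in metabolites]
            ann.append({"sample_id": sid, "role": ROLE_BLANK, "isolate": "", "replicate": r + 1})
    data = pd.DataFrame(columns, index=metabolites, dtype=float)
    samples = pd.DataFrame(ann).set_index("sample_id")
    return PeakTable(data=data, samples=samples)


def random_peak_table(rng: np.random.Generator, n_met=6, n_iso=3, n_rep=3, n_ctrl=4) -> PeakTable:
    mets = [f"m{k}" for k in range(n_met)]
    control = 10.0 ** rng.uniform(3, 6, n_met)
    values = {}
    for m_i, m in enumerate(mets):
        values[m] = {
            f"iso{j}": list(control[m_i] * rng.lognormal(0, 0.3, n_rep)) for j in range(n_iso)
        }
    ctrl = {m: list(control[i] * rng.lognormal(0, 0.3, n_ctrl)) for i, m in enumerate(mets)}
    return make_peak_table(values, control_values=ctrl)
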