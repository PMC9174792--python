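"""Packaged fixtures: the NLDM definition and small toy inputs.

``nldm_medium`` is the reconstructed Northen Lab Defined Medium: 64
metabolites in four equimolar concentration tiers (875 / 525 / 175 / 17.5
µM) plus the salt profile, Wolfe's vitamin and trace-mineral supplements and
the pH range. Tier membership is taken from the published description where
it is explicit; rows whose membership or tier had to be inferred from the
elemental-stoichiometry constraints (the per-tier C and N budgets) carry a
``source`` flag of ``tier_inferred`` or ``inferred`` — those rows are
synthetic reconstructions, not transcription.

``toy_peaks`` and ``toy_tree`` are hand-sized inputs for examples and smoke
tests.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from .exoprofile import PeakTable, read_peak_table
from .formulation import MediumDefinition, read_medium

FIXTURES = ("nldm_medium", "toy_peaks", "toy_tree")


def _data_path(name: str):
    return resources.files("exomedium.data").joinpath(name)


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``nldm_medium`` -> :class:`MediumDefinition`; ``toy_peaks`` ->
    :class:`PeakTable`; ``toy_tree`` -> ``dendropy.Tree``.
    """
    if name == "nldm_medium":
        with resources.as_file(_data_path("nldm_medium.json")) as p:
            medium: MediumDefinition = read_medium(p, dialect="json")
        return medium
    if name == "toy_peaks":
        with resources.as_file(_data_path("toy_peaks.tsv")) as peaks, resources.as_file(
            _data_path("toy_samples.tsv")
        ) as samples:
            table: PeakTable = read_peak_table(peaks, samples)
        return table
    if name == "toy_tree":
        with resources.as_file(_data_path("toy_tree.nwk")) as p:
            return dendropy.Tree.get(path=str(p), schema="newick", preserve_underscores=True)
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
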