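"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_replication_panel", "REPLICATION_PANEL_N", "REPLICATION_PANEL_N_COMBINED"]

# replication meta-analysis sample sizes behind the bundled panel:
# the four DXA cohorts sum to 17,787 directly measured participants
REPLICATION_PANEL_N = 17_787
REPLICATION_PANEL_N_COMBINED = 18_000  # the round figure used in power statements


def load_replication_panel() -> pd.DataFrame:
    """The 27-SNP body-composition discovery/replication panel.

    Per prioritised locus: lead SNP, best discovery trait, proximal gene
    label, GRCh37 coordinates, alleles, effect-allele frequency, the
    discovery (imputed-phenotype) effect/s.e./P, and the replication
    (directly measured meta-analysis) effect/s.e./Q-value.
    """
    with resources.files("proxygwas.data").joinpath("idxa_replication_panel.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})
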