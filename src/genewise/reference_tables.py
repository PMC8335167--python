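"""Bundled reference tables from the NMOSD gene-based association case study.

Three published per-gene result tables ship with the package as plain TSV:

* ``aqp4pos_stringent_panels`` — the two per-method panels of genes passing
  the stringent per-method threshold screen in the AQP4-seropositive
  stratum (method ``sum`` = VEGAS-style sum statistic, method ``set`` =
  set-based screen);
* ``aqp4pos_shared_gene_sets`` — the 50 AQP4-positive genes shared by both
  methods at p < 0.05 that passed the meta-Bonferroni rule, with both
  per-method p-values and the published combined p;
* ``aqp4neg_shared_gene_sets`` — the analogous 22 genes for the
  AQP4-seronegative stratum.

These tables serve as worked-example inputs: replaying the Fisher
combination and the selection rules on the printed per-method p-values
must reproduce the published combined p-values and gene selections.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_stringent_panels", "load_shared_gene_sets"]

# intersection size (meta-Bonferroni divisor) and set-method tested-gene
# count reported for each stratum of the case study
N_SHARED = {"aqp4pos": 315, "aqp4neg": 305}
N_TESTED_SET = {"aqp4pos": 16_532, "aqp4neg": 16_485}


def _load(name: str) -> pd.DataFrame:
    with resources.files("genewise.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_stringent_panels() -> pd.DataFrame:
    """Per-method stringent-screen panels (columns: method, gene, position,
    nsnps, p) for the AQP4-positive stratum."""
    return _load("aqp4pos_stringent_panels.tsv")


def load_shared_gene_sets(stratum: str) -> pd.DataFrame:
    """Shared significant gene sets for ``stratum`` in {"aqp4pos", "aqp4neg"}.

    Columns: gene, position, nsnp_set, p_set, nsnp_sum, p_sum, p_meta.
    """
    if stratum not in N_SHARED:
        raise ValueError(f"stratum must be one of {sorted(N_SHARED)}")
    df = _load(f"{stratum}_shared_gene_sets.tsv")
    return df[["gene", "position", "nsnp_set", "p_set", "nsnp_sum", "p_sum", "p_meta"]]
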