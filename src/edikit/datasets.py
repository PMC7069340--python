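"""Bundled reference datasets.

Two small published tables ship with the package: a GTEx bulk RNA-seq
cohort manifest (10 body sites across 4 tissues) and the statistically
significant differentially recoded sites from a Mann–Whitney/BH comparison
of tibial artery versus cerebellum samples at known recoding positions.
They serve as worked-example inputs and as ground truth for the summary
helpers below.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files("edikit.data").joinpath(name)


def load_gtex_cohort() -> pd.DataFrame:
    """Cohort manifest: tissue, body site, number of samples."""
    with resources.as_file(_path("gtex_cohort.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_differential_recoding() -> pd.DataFrame:
    """Significant differential recoding sites (artery vs cerebellum).

    Δ editing is mean(cerebellum) − mean(artery), so artery-high sites are
    negative. Columns: chr_position, gene, aa_change, delta_editing,
    pval_mw, padj_bh.
    """
    with resources.as_file(_path("artery_cerebellum_recoding.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def cohort_size(df: pd.DataFrame | None = None) -> int:
    """Total number of samples in the cohort manifest."""
    if df is None:
        df = load_gtex_cohort()
    return int(df["n_samples"].sum())


def differential_summary(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Counts from the differential recoding table: significant sites,
    distinct target genes, and the split into artery-high (negative Δ) and
    cerebellum-high (positive Δ) sites."""
    if df is None:
        df = load_differential_recoding()
    return {
        "n_sites": int(len(df)),
        "n_genes": int(df["gene"].nunique()),
        "n_artery_high": int((df["delta_editing"] < 0).sum()),
        "n_cerebellum_high": int((df["delta_editing"] > 0).sum()),
    }
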