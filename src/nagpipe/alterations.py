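"""Gene-level somatic alteration calling and burden (NAG) scoring.

A gene counts as altered in a tumor when it carries at least one somatic
non-synonymous variant or its copy-number log-R ratio (LRR) crosses the
gain/loss thresholds (gain: LRR > 0.5, loss: LRR < -0.5, both strict).
The number of altered genes within a fixed prognostic panel (NAG) is the
per-patient risk score, dichotomized at the first quartile or at an
absolute cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LRR_GAIN_THRESHOLD = 0.5
LRR_LOSS_THRESHOLD = -0.5

MAF_COLUMNS = ["sample_id", "gene", "protein_pos", "ref_aa", "alt_aa", "vaf"]

__all__ = [
    "VariantRecord",
    "AlterationMatrix",
    "call_copy_number_state",
    "build_alteration_matrix",
    "filter_recurrent_genes",
    "nag_score",
    "dichotomize_scores",
    "normalize_gene_symbol",
    "read_maf",
    "write_maf",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


@dataclass(frozen=True)
class VariantRecord:
    """A somatic non-synonymous variant in protein coordinates (1-based)."""

    sample_id: str
    gene: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    vaf: float

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"synonymous record {self.gene} p.{self.ref_aa}{self.protein_pos}"
                f"{self.alt_aa}: only non-synonymous variants are accepted"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")


@dataclass
class AlterationMatrix:
    """Binary patients x genes indicator of any somatic alteration.

    ``indicator`` rows are sample ids, columns the ordered gene universe
    (normalized symbols, sorted unless an explicit universe was supplied).
    """

    indicator: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.indicator.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("alteration indicator entries must be 0/1")
        self.indicator = self.indicator.astype(np.int8)

    @property
    def gene_universe(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.indicator.index)


def normalize_gene_symbol(symbol: str) -> str:
    """Single normalization pass: trim whitespace and uppercase."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# copy-number calling
# ---------------------------------------------------------------------------

def call_copy_number_state(lrr_value):
    """Classify a gene-level LRR as 'loss', 'neutral' or 'gain'.

    Thresholds are strict: values exactly at +/-0.5 are neutral.
    Accepts scalars or arrays; rejects non-finite input.
    """
    arr = np.asarray(lrr_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite LRR value")
    state = np.where(
        arr > LRR_GAIN_THRESHOLD, "gain",
        np.where(arr < LRR_LOSS_THRESHOLD, "loss", "neutral"),
    )
    return state.item() if np.isscalar(lrr_value) or arr.ndim == 0 else state


# ---------------------------------------------------------------------------
# alteration matrix
# ---------------------------------------------------------------------------

def build_alteration_matrix(
    variants: pd.DataFrame,
    lrr: pd.DataFrame | None = None,
    gene_universe: list[str] | None = None,
    samples: list[str] | None = None,
) -> AlterationMatrix:
    """Combine variants and copy-number states into the binary matrix.

    Parameters
    ----------
    variants
        MAF-like table with at least ``sample_id`` and ``gene`` columns.
    lrr
        gene x sample LRR matrix (genes as index, sample ids as columns).
    gene_universe
        Column order; defaults to the sorted union of genes seen in either
        input.  Genes absent from both inputs stay all-zero columns.
    samples
        Row order; defaults to the sorted union of sample ids.  A variant
        naming a sample outside this list raises with the offending id.
    """
    var_genes = [normalize_gene_symbol(g) for g in variants["gene"]] if len(variants) else []
    var_samples = [str(s) for s in variants["sample_id"]] if len(variants) else []
    lrr_genes = [normalize_gene_symbol(g) for g in lrr.index] if lrr is not None else []
    lrr_samples = [str(c) for c in lrr.columns] if lrr is not None else []

    if gene_universe is None:
        gene_universe = sorted(set(var_genes) | set(lrr_genes))
    else:
        gene_universe = [normalize_gene_symbol(g) for g in gene_universe]
    if not gene_universe:
        raise ValueError("gene universe is empty")
    if samples is None:
        samples = sorted(set(var_samples) | set(lrr_samples))
    else:
        samples = [str(s) for s in samples]
        unknown = sorted(set(var_samples) - set(samples))
        if unknown:
            raise ValueError(f"variant sample ids not in cohort: {unknown}")

    sample_pos = {s: i for i, s in enumerate(samples)}
    gene_pos = {g: j for j, g in enumerate(gene_universe)}
    ind = np.zeros((len(samples), len(gene_universe)), dtype=np.int8)

    for s, g in zip(var_samples, var_genes):
        si = sample_pos.get(s)
        if si is None:
            raise ValueError(f"variant sample id not in cohort: {s!r}")
        gj = gene_pos.get(g)
        if gj is not None:
            ind[si, gj] = 1

    if lrr is not None and len(lrr):
        vals = lrr.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite LRR value")
        if len(set(lrr_genes)) != len(lrr_genes):
            raise ValueError("duplicate genes in LRR matrix")
        altered = (vals > LRR_GAIN_THRESHOLD) | (vals < LRR_LOSS_THRESHOLD)
        alt_df = pd.DataFrame(altered, index=lrr_genes, columns=lrr_samples)
        aligned = alt_df.reindex(index=gene_universe, columns=samples,
                                 fill_value=False).fillna(False)
        ind = np.maximum(ind, aligned.T.to_numpy(dtype=np.int8))

    mat = pd.DataFrame(ind, index=pd.Index(samples, name="sample_id"),
                       columns=pd.Index(gene_universe, name="gene"))
    return AlterationMatrix(indicator=mat)


def filter_recurrent_genes(matrix: AlterationMatrix, min_patients: int = 2) -> AlterationMatrix:
    """Drop genes altered in fewer than ``min_patients`` tumors."""
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    counts = matrix.indicator.sum(axis=0)
    keep = counts.index[counts >= min_patients]
    logger.info("filter_recurrent_genes: %d of %d genes kept (min_patients=%d)",
                len(keep), matrix.indicator.shape[1], min_patients)
    return AlterationMatrix(indicator=matrix.indicator[keep])


# ---------------------------------------------------------------------------
# NAG scoring
# ---------------------------------------------------------------------------

def nag_score(matrix: AlterationMatrix, panel) -> pd.Series:
    """Number of altered genes within ``panel`` per patient.

    Panel genes missing from the matrix universe contribute 0 (logged);
    an entirely disjoint panel is an error.
    """
    panel = [normalize_gene_symbol(g) for g in panel]
    if not panel:
        raise ValueError("empty panel")
    present = [g for g in dict.fromkeys(panel) if g in set(matrix.gene_universe)]
    missing = sorted(set(panel) - set(present))
    if not present:
        raise ValueError("panel is disjoint from the gene universe")
    if missing:
        logger.warning("nag_score: %d panel genes absent from universe: %s",
                       len(missing), ", ".join(missing[:10]))
    scores = matrix.indicator[present].sum(axis=1).astype(int)
    scores.name = "nag"
    return scores


def dichotomize_scores(
    scores: pd.Series,
    quartile_cutoff: float = 0.25,
    threshold: float | None = None,
) -> pd.Series:
    """Label patients 'low'/'high' burden.

    Quantile mode (default): low iff score <= Q1 (linear-interpolation
    quantile, ties to 'low').  Absolute mode: ``threshold`` t given,
    high iff score >= t.
    """
    scores = pd.Series(scores)
    if threshold is not None:
        labels = np.where(scores.to_numpy() >= threshold, "high", "low")
        return pd.Series(labels, index=scores.index, name="nag_group")
    if scores.nunique() < 2:
        raise ValueError("constant scores: no quartile split possible")
    if len(scores) < 4:
        raise ValueError("need >= 4 observations for a data-driven quartile cutoff")
    q = float(np.quantile(scores.to_numpy(dtype=float), quartile_cutoff))  # type 7
    labels = np.where(scores.to_numpy() <= q, "low", "high")
    if len(set(labels)) < 2:
        raise ValueError("quartile cutoff does not split the cohort")
    return pd.Series(labels, index=scores.index, name="nag_group")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str,
                                            "ref_aa": str, "alt_aa": str},
                     float_precision="round_trip")
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} lacks columns: {missing}")
    return df[MAF_COLUMNS]


def write_maf(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False, columns=MAF_COLUMNS,
                    float_format="%.17g")


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a gene x sample (or sample x gene) TSV matrix, first column index."""
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")
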