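"""Normalisation, dual-probe aggregation and mutation/virus calls.

Molecule counts are made comparable across samples by converting each
expression marker to a depth-free relative abundance (counts divided by the
sample's total expression molecules), scaling to molecules-per-10k, and
applying ``log2(1 + x)``.  The interpretability floor (5000 molecules)
still allows roughly a tenfold spread in depth between samples, so
depth-invariance is the one property the normalisation must guarantee.

Genes covered by two probe pairs are reported as the mean of the two pair
values on the log scale.  Mutation and virus-status loci are reported as a
variant fraction ``variant / (variant + reference)`` with a configurable
positivity threshold and minimum depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelDefinition
from .readproc import UmiCountMatrix

#: scale factor: normalised values are molecules per 10,000
NORM_SCALE = 10_000

DEFAULT_VARIANT_FRACTION = 0.1
DEFAULT_MIN_DEPTH = 20


class NormalizationError(ValueError):
    pass


def normalize(counts: UmiCountMatrix,
              panel: PanelDefinition | None = None,
              include_non_interpretable: bool = False) -> pd.DataFrame:
    """Per-sample log2(1 + 1e4 * count / total) over expression markers.

    When a panel is supplied, MUTATION-group probes are excluded from both
    the numerator and the per-sample total, so the pre-log relative
    abundances sum to 1 over expression markers.  Non-interpretable samples
    (< 5000 molecules) are dropped with a warning unless
    ``include_non_interpretable`` is set.
    """
    mat = counts.counts
    if panel is not None:
        keep = [m for m in mat.columns
                if m in {p.marker_id for p in panel.expression_probes}]
        mat = mat[keep]
    ok = counts.interpretable
    if not include_non_interpretable:
        dropped = [s for s in mat.index if not ok.loc[s]]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} non-interpretable sample(s) "
                f"(< 5000 molecules): {dropped[:5]}", stacklevel=2)
        mat = mat.loc[[s for s in mat.index if ok.loc[s]]]
    if mat.shape[0] == 0:
        raise NormalizationError("no interpretable samples to normalize")
    totals = mat.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise NormalizationError("sample with zero assigned molecules")
    rel = mat.div(totals, axis=0)
    return np.log2(1.0 + NORM_SCALE * rel)


def delog(values: pd.DataFrame | pd.Series):
    """Invert the log transform back to molecules-per-10k."""
    return 2.0 ** values - 1.0


def aggregate_dual_probes(expr: pd.DataFrame,
                          panel: PanelDefinition) -> pd.DataFrame:
    """Collapse probe-pair columns to gene level (mean of dual pairs).

    Input columns are marker_ids (``GENE_1``, ``GENE_2``); output columns
    are gene names in panel order.  Column order of the input is irrelevant.
    """
    id_to_gene = {p.marker_id: p.gene for p in panel.expression_probes}
    genes = panel.expression_markers
    cols: dict[str, pd.Series] = {}
    for gene in genes:
        members = [m for m in expr.columns if id_to_gene.get(m) == gene]
        if not members:
            continue
        cols[gene] = expr[members].mean(axis=1)
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class MutationCall:
    sample: str
    locus: str
    variant_umis: int
    reference_umis: int
    variant_fraction: float  # nan when depth == 0
    depth: int
    positive: bool


def call_mutations(counts: UmiCountMatrix, panel: PanelDefinition,
                   variant_fraction_threshold: float = DEFAULT_VARIANT_FRACTION,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> list[MutationCall]:
    """Variant fraction and call per sample and mutation/virus locus.

    A locus is called positive when its variant fraction reaches the
    threshold at sufficient molecular depth (variant + reference UMIs).
    """
    calls: list[MutationCall] = []
    for locus in panel.mutation_loci:
        var_id, ref_id = f"{locus}_1", f"{locus}_2"
        for sample in counts.samples:
            v = int(counts.counts.loc[sample, var_id])
            r = int(counts.counts.loc[sample, ref_id])
            depth = v + r
            frac = v / depth if depth > 0 else float("nan")
            positive = (depth >= min_depth and depth > 0
                        and frac >= variant_fraction_threshold)
            calls.append(MutationCall(sample, locus, v, r, frac, depth,
                                      positive))
    return calls


def mutation_report(calls: list[MutationCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": c.sample, "locus": c.locus,
        "variant_umis": c.variant_umis, "reference_umis": c.reference_umis,
        "fraction": c.variant_fraction, "depth": c.depth, "call": c.positive,
    } for c in calls])
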