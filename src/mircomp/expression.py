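"""Expression normalization, miRNA-mRNA correlation, and independent contrasts.

Counts are normalized to reads per million (small-RNA libraries) or
transcripts per million (length-corrected mRNA libraries).  Functional
miRNA-mRNA pairs are correlated across individuals (Pearson), and again
across species after phylogenetically independent contrasts, which remove
the shared-ancestry covariance under a Brownian-motion model before the
correlation (computed through the origin, as contrasts have no defined
sign or mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult, chi2_gof
from .tree import SpeciesTree


def tpm_normalize(counts: pd.DataFrame, lengths: dict[str, float]) -> pd.DataFrame:
    """Transcripts per million: (c/L) / sum(c/L) * 1e6 per sample."""
    missing = [f for f in counts.index if f not in lengths]
    if missing:
        raise ValueError(f"missing lengths for: {', '.join(map(str, missing[:5]))}")
    L = pd.Series({f: float(lengths[f]) for f in counts.index})
    if (L <= 0).any():
        bad = L.index[L <= 0][0]
        raise ValueError(f"non-positive length for feature {bad}")
    rate = counts.div(L, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad} has zero total count")
    return rate.div(totals, axis=1) * 1e6


def rpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: c * 1e6 / column total."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad} has zero total count")
    return counts.div(totals, axis=1) * 1e6


def log2p1(values):
    return np.log2(np.asarray(values, dtype=float) + 1.0)


def pair_correlations(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    functional_pairs,
    transform: str = "log2p1",
) -> pd.DataFrame:
    """Pearson r (and t-distribution p, n-2 df) per functional pair.

    Pairs with zero variance in either vector get NA and are excluded from
    sign counts downstream.
    """
    shared = [s for s in mirna_expr.columns if s in set(mrna_expr.columns)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    rows = []
    for mirna, gene in functional_pairs:
        if mirna not in mirna_expr.index or gene not in mrna_expr.index:
            continue
        x = mirna_expr.loc[mirna, shared].to_numpy(dtype=float)
        y = mrna_expr.loc[gene, shared].to_numpy(dtype=float)
        if transform == "log2p1":
            x, y = log2p1(x), log2p1(y)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((mirna, gene, math.nan, math.nan, len(shared)))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((mirna, gene, float(r), float(p), len(shared)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "p", "n"])


@dataclass
class Contrast:
    node_id: str
    value: float
    variance: float  # sum of (adjusted) branch lengths at the node


def pic(tree: SpeciesTree, tip_values: dict[str, float]) -> list[Contrast]:
    """Felsenstein's phylogenetically independent contrasts.

    Standard pruning: at each internal node the contrast is the difference
    of the two daughter values standardized by the square root of the sum
    of their (extended) branch lengths; the node's ancestral value is the
    precision-weighted mean and its parent branch is extended by
    b1*b2/(b1+b2).  Returns n_tips - 1 standardized contrasts in
    post-order.
    """
    missing = [t for t in tree.tip_names if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip value(s): {', '.join(missing)}")
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[Contrast] = []
    for node in tree.postorder():
        if node.is_leaf():
            values[id(node)] = float(tip_values[node.taxon.label])
            bl = node.edge.length if node.parent_node is not None else 0.0
            if node.parent_node is not None and (bl is None or bl <= 0):
                raise ValueError(
                    f"branch above {node.taxon.label} must have length > 0"
                )
            lengths[id(node)] = float(bl or 0.0)
        else:
            left, right = node.child_nodes()
            b1, b2 = lengths[id(left)], lengths[id(right)]
            x1, x2 = values[id(left)], values[id(right)]
            var = b1 + b2
            contrasts.append(
                Contrast(tree.node_id(node), (x1 - x2) / math.sqrt(var), var)
            )
            values[id(node)] = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2)
            own = node.edge.length if node.parent_node is not None else 0.0
            if node.parent_node is not None and (own is None or own <= 0):
                raise ValueError("zero/missing internal branch length")
            lengths[id(node)] = float(own or 0.0) + b1 * b2 / (b1 + b2)
    return contrasts


def pic_correlation(contrasts_x: list[Contrast], contrasts_y: list[Contrast]) -> float:
    """Correlation of two contrast sets through the origin."""
    nodes_x = [c.node_id for c in contrasts_x]
    nodes_y = [c.node_id for c in contrasts_y]
    if nodes_x != nodes_y:
        raise ValueError("contrast sets computed on different node sets")
    x = np.array([c.value for c in contrasts_x])
    y = np.array([c.value for c in contrasts_y])
    denom = math.sqrt(float((x**2).sum()) * float((y**2).sum()))
    if denom == 0:
        return math.nan
    return float((x * y).sum() / denom)


def species_means(
    expr: pd.DataFrame, species_of_sample: dict[str, str], transform: str = "log2p1"
) -> pd.DataFrame:
    """Per-species mean of (optionally log2(x+1)) normalized expression."""
    data = expr.copy()
    if transform == "log2p1":
        data = np.log2(data + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    cols = {}
    for sample in data.columns:
        cols.setdefault(species_of_sample[sample], []).append(sample)
    return pd.DataFrame(
        {sp: data[cs].mean(axis=1) for sp, cs in sorted(cols.items())}
    )


def pic_pair_correlations(
    mirna_by_species: pd.DataFrame,
    mrna_by_species: pd.DataFrame,
    functional_pairs,
    tree: SpeciesTree,
) -> pd.DataFrame:
    """Across-species correlation of pairs after independent contrasts."""
    rows = []
    for mirna, gene in functional_pairs:
        if mirna not in mirna_by_species.index or gene not in mrna_by_species.index:
            continue
        cx = pic(tree, mirna_by_species.loc[mirna].to_dict())
        cy = pic(tree, mrna_by_species.loc[gene].to_dict())
        rows.append((mirna, gene, pic_correlation(cx, cy), len(cx)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "r", "n_contrasts"])


def sign_bias_test(correlations) -> tuple[int, int, TestResult]:
    """Excess of negative over positive correlations against 50:50.

    NAs and exact zeros are excluded; the test is a df-1 goodness of fit
    without continuity correction.
    """
    rs = [r for r in correlations if not (r is None or math.isnan(r) or r == 0)]
    if len(rs) < 2:
        raise ValueError("fewer than 2 usable correlations")
    n_neg = sum(1 for r in rs if r < 0)
    n_pos = len(rs) - n_neg
    res = chi2_gof([n_neg, n_pos], [0.5, 0.5])
    return n_neg, n_pos, res
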