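"""Amino-acid composition and the thermophile/mesophile comparison.

The Kruskal–Wallis rank test is implemented here in full (ranking with
midrank ties, the H statistic, and the tie-corrected statistic referred to
a chi-square distribution with k-1 degrees of freedom) so the core
statistical claim does not lean on a statistics package; only the
chi-square upper tail comes from the regularized incomplete gamma function.

One value per strain enters each test: a strain with several copies of a
subunit contributes the mean composition of its copies, avoiding
pseudo-replication. No multiple-testing correction is applied (plain alpha
levels); the number of tests performed is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc, gammaincc

from .records import STANDARD_RESIDUES, ProteinRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionVector:
    """Residue percentages of one protein (X excluded from both sides)."""

    protein_id: str
    percent: dict[str, float]


@dataclass(frozen=True)
class KWResult:
    H: float
    H_corrected: float
    df: int
    p: float
    group_summaries: tuple[tuple[float, float], ...]  # (mean, sd) per group


def composition(seq: ProteinRecord) -> CompositionVector:
    """Percentage of each standard residue; X positions are ignored."""
    counted = [r for r in seq.sequence if r != "X"]
    if not counted:
        raise ValueError(f"{seq.protein_id}: sequence is all X")
    n = len(counted)
    percent = {r: 100.0 * counted.count(r) / n for r in STANDARD_RESIDUES}
    return CompositionVector(seq.protein_id, percent)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned their midrank, by sorting."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        ranks[order[i : j + 1]] = midrank
        i = j + 1
    return ranks


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized incomplete gamma."""
    return float(gammaincc(df / 2.0, x / 2.0))


def chi2_sf_df1(x: float) -> float:
    """Closed form for df=1 (cross-check of :func:`chi2_sf`)."""
    return float(erfc(np.sqrt(x / 2.0)))


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """Kruskal–Wallis H test over k groups.

    H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2 on midranks; the
    tie-corrected statistic divides by 1 - sum(t^3 - t)/(N^3 - N). If every
    pooled value is identical the test is undefined and p = 1 is returned
    by convention with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least three values in total")
    sizes = [len(g) for g in groups]
    summaries = tuple(
        (float(np.mean(g)), float(np.std(g, ddof=1)) if len(g) > 1 else 0.0)
        for g in groups
    )
    df = len(groups) - 1

    ranks = _midranks(pooled)
    expected = (n_total + 1) / 2.0
    h = 0.0
    offset = 0
    for size in sizes:
        group_mean = ranks[offset : offset + size].mean()
        h += size * (group_mean - expected) ** 2
        offset += size
    h *= 12.0 / (n_total * (n_total + 1))

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    tie_factor = 1.0 - tie_sum / (n_total**3 - n_total)
    if tie_factor == 0.0:
        warnings.warn("all values identical across groups; p = 1 by convention")
        return KWResult(h, 0.0, df, 1.0, summaries)
    h_corrected = h / tie_factor
    p = chi2_sf(h_corrected, df)
    return KWResult(h, h_corrected, df, p, summaries)


def compare_groups(
    family_name: str,
    thermo: list[CompositionVector],
    meso: list[CompositionVector],
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """Per-residue Kruskal–Wallis comparison for one PBP subunit.

    Returns a table sorted by p with one row per residue: group means +- sd
    (formatted like the published composition tables) and significance
    flags at each alpha level. Skipped with a warning (empty table) if
    either group has fewer than 2 strains.
    """
    if len(thermo) < 2 or len(meso) < 2:
        log.warning(
            "%s: fewer than 2 strains in a group (thermo=%d, meso=%d); test skipped",
            family_name, len(thermo), len(meso),
        )
        return pd.DataFrame(
            columns=["family", "residue", "thermophile", "mesophile", "H", "p"]
            + [f"sig_{a}" for a in alphas]
        )
    rows = []
    for residue in STANDARD_RESIDUES:
        t_values = [v.percent[residue] for v in thermo]
        m_values = [v.percent[residue] for v in meso]
        result = kruskal_wallis([t_values, m_values])
        (t_mean, t_sd), (m_mean, m_sd) = result.group_summaries
        row = {
            "family": family_name,
            "residue": residue,
            "thermophile": f"{t_mean:.2f} ± {t_sd:.2f}%",
            "mesophile": f"{m_mean:.2f} ± {m_sd:.2f}%",
            "H": result.H_corrected,
            "p": result.p,
        }
        for alpha in alphas:
            row[f"sig_{alpha}"] = result.p <= alpha
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    log.info("%s: %d rank tests performed (no multiplicity correction)",
             family_name, len(rows))
    return table
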