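"""FPKM, library-presence partitions, differential abundance and qPCR math.

Differential abundance between two replicate-free libraries is tested with
the Audic–Claverie conditional test: under equal per-library Poisson rates,
the count in the second library given the count in the first follows a
negative-binomial law, whose tail probabilities give an exact two-sided
p-value.  q-values are Benjamini–Hochberg adjusted.  Note that the test
assumes counting (Poisson) noise only; biological overdispersion between
libraries inflates its significance, a caveat shared by every
single-replicate contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import CountTable

__all__ = [
    "ExpressionMatrix",
    "VennResult",
    "DALRecord",
    "fpkm",
    "venn_partition",
    "audic_claverie_p",
    "dal_test",
    "dal_call",
    "ddct",
]

DEFAULT_PRESENCE_FPKM = 0.1
DEFAULT_DAL_Q = 0.01
DEFAULT_DAL_LOG2FC = 1.0
DEFAULT_PSEUDOCOUNT = 1e-6  # on the depth-normalised rate scale


@dataclass
class ExpressionMatrix:
    """Transcript x library FPKM values."""

    fpkm: pd.DataFrame
    presence_threshold: float = DEFAULT_PRESENCE_FPKM

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    def present(self, threshold: float | None = None) -> pd.DataFrame:
        """Boolean presence mask (FPKM strictly above the threshold)."""
        thr = self.presence_threshold if threshold is None else threshold
        return self.fpkm > thr


def fpkm(
    counts: CountTable, lengths: Mapping[str, int] | pd.Series
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm[t, l] = counts[t, l] * 1e9 / (library_totals[l] * length[t])``
    """
    lengths = pd.Series(lengths).reindex(counts.counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:3])
        raise KeyError(f"missing spliced lengths for transcripts {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = counts.library_totals.astype(float)
    if (totals <= 0).any():
        raise ValueError("zero library total; FPKM undefined")
    values = (
        counts.counts.values * 1e9 / np.outer(lengths.values, totals.values)
    )
    return ExpressionMatrix(
        fpkm=pd.DataFrame(
            values, index=counts.counts.index, columns=counts.counts.columns
        )
    )


@dataclass
class VennResult:
    """Library-presence partition of a set of transcripts."""

    membership: dict[str, frozenset]
    subset_counts: dict[frozenset, int]
    n_all_libraries: int
    library_specific: dict[str, int]
    seed_specific: int | None  # None when seed/root/leaf roles are unknown
    n_present_anywhere: int


def venn_partition(
    em: ExpressionMatrix,
    ids: Sequence[str],
    threshold: float | None = None,
    seed_libraries: Sequence[str] | None = None,
) -> VennResult:
    """Partition transcripts by the subset of libraries they appear in.

    A transcript is present in a library iff its FPKM exceeds the
    threshold (default 0.1).  ``seed_libraries`` may name the developing-
    seed libraries, in which case the seed-specific tally (present in >= 1
    seed library, absent everywhere else) is reported.
    """
    ids = [i for i in ids if i in em.fpkm.index]
    mask = em.present(threshold).loc[ids]
    libs = list(em.fpkm.columns)
    membership = {
        tid: frozenset(l for l in libs if mask.at[tid, l]) for tid in ids
    }
    subset_counts: dict[frozenset, int] = {}
    for s in membership.values():
        subset_counts[s] = subset_counts.get(s, 0) + 1
    all_libs = frozenset(libs)
    library_specific = {
        l: subset_counts.get(frozenset([l]), 0) for l in libs
    }
    seed_specific = None
    if seed_libraries is not None:
        seeds = set(seed_libraries)
        others = set(libs) - seeds
        seed_specific = sum(
            1
            for s in membership.values()
            if s and s <= seeds and not (s & others)
        )
    return VennResult(
        membership=membership,
        subset_counts=subset_counts,
        n_all_libraries=subset_counts.get(all_libs, 0),
        library_specific=library_specific,
        seed_specific=seed_specific,
        n_present_anywhere=sum(1 for s in membership.values() if s),
    )


# ---------------------------------------------------------------------------
# Differential abundance


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic–Claverie p-value for counts ``x`` (depth ``n1``) and
    ``y`` (depth ``n2``).

    Under equal Poisson rates, ``P(y | x) = (n2/n1)^y (x+y)! /
    (x! y! (1 + n2/n1)^(x+y+1))``, which is the NegBinom(x+1, n1/(n1+n2))
    pmf at y; the two-sided p doubles the smaller tail (capped at 1).
    """
    p = n1 / (n1 + n2)
    lo = stats.nbinom.cdf(y, x + 1, p)
    hi = stats.nbinom.sf(y - 1, x + 1, p)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass(frozen=True)
class DALRecord:
    """A differentially abundant transcript between two libraries."""

    transcript_id: str
    library_pair: tuple[str, str]
    log2fc: float
    p_value: float
    q_value: float


def dal_test(
    counts: CountTable,
    pair: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-transcript statistics for one two-library contrast.

    log2 fold change uses depth-normalised rates with a small pseudocount
    (stability for zero counts); p-values are Audic–Claverie, q-values BH.
    """
    lib_i, lib_j = pair
    for lib in pair:
        if lib not in counts.counts.columns:
            raise KeyError(f"library {lib} not in count table")
    x = counts.counts[lib_i].values
    y = counts.counts[lib_j].values
    n1 = float(counts.library_totals[lib_i])
    n2 = float(counts.library_totals[lib_j])
    log2fc = np.log2((x / n1 + pseudocount) / (y / n2 + pseudocount))
    pvals = np.array([audic_claverie_p(int(a), int(b), n1, n2) for a, b in zip(x, y)])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "q_value": qvals},
        index=counts.counts.index,
    )


def dal_call(
    counts: CountTable,
    pair: tuple[str, str],
    q_max: float = DEFAULT_DAL_Q,
    min_log2fc: float = DEFAULT_DAL_LOG2FC,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DALRecord]:
    """Differentially abundant transcripts: q < 0.01 AND |log2FC| > 1."""
    table = dal_test(counts, pair, pseudocount)
    kept = table[(table.q_value < q_max) & (table.log2fc.abs() > min_log2fc)]
    return [
        DALRecord(
            transcript_id=tid,
            library_pair=tuple(pair),
            log2fc=float(row.log2fc),
            p_value=float(row.p_value),
            q_value=float(row.q_value),
        )
        for tid, row in kept.iterrows()
    ]


def ddct(
    ct_target: tuple[float, float], ct_ref: tuple[float, float]
) -> float:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``ct_target`` and ``ct_ref`` are (treated, control) cycle-threshold
    values of the target and the reference gene.  Returns
    ``2 ** -((ct_t,treated - ct_r,treated) - (ct_t,control - ct_r,control))``.
    """
    tt, tc = ct_target
    rt, rc = ct_ref
    if not all(np.isfinite([tt, tc, rt, rc])):
        raise ValueError("Ct values must be finite")
    ddct_value = (tt - rt) - (tc - rc)
    return float(2.0 ** (-ddct_value))
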