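"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity from first principles through a code path
deliberately different from the implementation: per-frame ATG x stop
enumeration for ORFs, per-base membership arrays for splicing differences,
element-wise loops for FPKM, definitional formulas for correlations, the
printed conditional-probability formula for the two-library count test, and
offset-by-offset pure-Python scoring for complementarity.
"""

from __future__ import annotations

import math

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# ORF oracle: enumerate (ATG, stop) codon pairs per frame.


def orf_oracle(seq: str):
    """Return (start, end, complete) of the longest ORF, ties to the
    smallest start; complete ORFs always beat open stretches."""
    seq = seq.upper()
    n = len(seq)
    complete, open_ = [], []
    for f in range(3):
        frame_end = f + 3 * ((n - f) // 3)
        codon_starts = list(range(f, n - 2, 3))
        atgs = [i for i in codon_starts if seq[i : i + 3] == "ATG"]
        stops = [i for i in codon_starts if seq[i : i + 3] in STOPS]
        for a in atgs:
            later = [s for s in stops if s > a]
            if later:
                complete.append((a, min(later) + 3))
            else:
                open_.append((a, frame_end))
    pool = complete if complete else open_
    if not pool:
        return (0, 0, False)
    best = sorted(pool, key=lambda c: (-(c[1] - c[0]), c[0]))[0]
    return (best[0], best[1], bool(complete))


# ---------------------------------------------------------------------------
# AS difference-region oracle: per-base membership arrays.


def _mem_array(exons, lo, hi):
    arr = np.full(hi - lo, ord("O"), dtype=np.uint8)
    span = (exons[0][0], exons[-1][1])
    arr[span[0] - lo : span[1] - lo] = ord("I")
    for s, e in exons:
        arr[s - lo : e - lo] = ord("E")
    return arr


def as_events_oracle(a, b):
    """Label every maximal genomic difference region between two exon
    chains by its per-base membership pattern.  Returns a list of
    (event_type, (start, end))."""
    lo = min(a.start, b.start)
    hi = max(a.end, b.end)
    if a.exons == b.exons:
        return []
    if len(a.exons) == 1 and len(b.exons) == 1:
        return []
    ma = _mem_array(a.exons, lo, hi)
    mb = _mem_array(b.exons, lo, hi)
    diff = ma != mb
    events = []
    i = 0
    n = hi - lo
    while i < n:
        if not diff[i]:
            i += 1
            continue
        j = i
        while j < n and diff[j]:
            j += 1
        seg = slice(i, j)
        pats = set(zip(ma[seg].tolist(), mb[seg].tolist()))
        has_o = any(ord("O") in p for p in pats)
        if has_o:
            tl, tr = i == 0, j == n
            if tl and tr:
                etype = "other"
            elif tl:
                etype = "TSS" if a.strand == "+" else "TTS"
            else:
                etype = "TTS" if a.strand == "+" else "TSS"
        elif len(pats) == 1:
            left = chr(ma[i - 1])
            right = chr(ma[j])
            if left == "E" and right == "E":
                etype = "IR"
            elif left == "I" and right == "I":
                etype = "ES"
            else:
                etype = "AE"
        else:
            etype = "other"
        events.append((etype, (lo + i, lo + j)))
        i = j
    return events


# ---------------------------------------------------------------------------
# FPKM oracle: element-wise recomputation.


def fpkm_oracle(counts: np.ndarray, lengths, totals) -> np.ndarray:
    out = np.zeros(counts.shape, dtype=float)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            out[i, j] = counts[i, j] * 1e9 / (totals[j] * lengths[i])
    return out


# ---------------------------------------------------------------------------
# Correlation oracle: definitional formulas + t reference distribution.


def _t_sf(t: float, df: int) -> float:
    from scipy.stats import t as tdist  # reference distribution only

    return float(tdist.sf(t, df))


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
    r_ = min(1 - 1e-15, max(-1 + 1e-15, r))
    t = abs(r_) * math.sqrt((n - 2) / (1 - r_ * r_))
    return r, 2 * _t_sf(t, n - 2)


def _avg_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
        i = j
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(_avg_ranks(x), _avg_ranks(y))


# ---------------------------------------------------------------------------
# Audic-Claverie oracle: the printed formula via log-gamma.


def audic_claverie_oracle(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided p from P(y|x) = (n2/n1)^y (x+y)! / (x! y! (1+n2/n1)^(x+y+1)),
    summed term by term."""

    def log_p(yy: int) -> float:
        return (
            yy * math.log(n2 / n1)
            + math.lgamma(x + yy + 1)
            - math.lgamma(x + 1)
            - math.lgamma(yy + 1)
            - (x + yy + 1) * math.log1p(n2 / n1)
        )

    lo = sum(math.exp(log_p(k)) for k in range(0, y + 1))
    # upper tail: sum to a generous bound beyond which terms are negligible
    mean = (x + 1) * n2 / n1
    upper = int(max(y, mean) + 20 * math.sqrt(mean + 10) + 50)
    hi = sum(math.exp(log_p(k)) for k in range(y, upper + 1))
    return min(1.0, 2.0 * min(lo, hi))


# ---------------------------------------------------------------------------
# Complementarity oracle: pure-Python offset loop.

_PAIRS = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}


def complementarity_oracle(lnc: str, mrna: str) -> float:
    a = lnc.upper()[::-1]
    b = mrna.upper()
    if len(a) > len(b):
        a, b = b, a  # pair weights are symmetric
    best = 0.0
    for k in range(len(b) - len(a) + 1):
        s = 0.0
        for i, ca in enumerate(a):
            s += _PAIRS.get((ca, b[k + i]), 0.0)
        s /= len(a)
        if s < best:
            best = s
    return best


# ---------------------------------------------------------------------------
# Translation oracle for the truncated-isoform screen.


def longest_protein_oracle(seq: str):
    """(aa_length, complete) of the longest translated ORF using
    Biopython's translation, scanning the three forward frames."""
    from Bio.Seq import Seq

    seq = seq.upper()
    best_complete, best_open = 0, 0
    for f in range(3):
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        if not sub:
            continue
        prot = str(Seq(sub).translate())
        chunks = prot.split("*")
        for idx, chunk in enumerate(chunks):
            m = chunk.find("M")
            if m < 0:
                continue
            aa = len(chunk) - m
            if idx < len(chunks) - 1:  # a stop codon follows
                best_complete = max(best_complete, aa)
            else:
                best_open = max(best_open, aa)
    if best_complete:
        return best_complete, True
    return best_open, False
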