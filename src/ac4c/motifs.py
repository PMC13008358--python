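"""Simplified de-novo k-mer motif discovery in peak sequences.

Each candidate k-mer is scored under the ZOOPS model (zero-or-one occurrence
per sequence: a sequence counts once no matter how many times it contains
the k-mer) and tested for enrichment in foreground over background sequences
with the upper-tail hypergeometric probability, BH-corrected across all 4^k
candidates.  This is the scoring principle of HOMER-style enrichment without
the degenerate-motif optimisation; fixed-length exact k-mers only.

Reverse-complement collapsing is off by default: an RNA modification is
strand-defined, so the motif lives on the sense strand.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .peaks import bh_adjust

__all__ = [
    "MotifResult",
    "zoops_count",
    "hypergeometric_enrichment",
    "discover_motifs",
    "markov_shuffle",
    "random_sequences",
    "plant_motif",
]

_BASES = "ACGT"

# IUPAC degenerate nucleotide codes (ACGT map to themselves)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class MotifResult:
    """Enrichment of one k-mer: ZOOPS counts and hypergeometric p/q."""

    kmer: str
    fg_with: int
    bg_with: int
    fg_n: int
    bg_n: int
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not 0 <= self.fg_with <= self.fg_n:
            raise ValueError("fg_with outside [0, fg_n]")
        if not 0 <= self.bg_with <= self.bg_n:
            raise ValueError("bg_with outside [0, bg_n]")


def _iupac_regex(kmer: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in kmer))


def zoops_count(sequences: Sequence[str], kmer: str) -> int:
    """Number of sequences containing >= 1 occurrence of ``kmer``.

    Plain ACGT k-mers use exact substring search; k-mers containing IUPAC
    degeneracy codes are matched by expansion.  Sequences are uppercased;
    characters outside ACGT never match (masking).
    """
    if not kmer:
        raise ValueError("empty kmer")
    kmer = kmer.upper()
    if any(c not in IUPAC for c in kmer):
        raise ValueError(f"invalid nucleotide code in {kmer!r}")
    degenerate = any(c not in _BASES for c in kmer)
    if degenerate:
        pat = _iupac_regex(kmer)
        return sum(1 for s in sequences if pat.search(s.upper()) is not None)
    return sum(1 for s in sequences if kmer in s.upper())


def hypergeometric_enrichment(
    fg_with: int, fg_n: int, bg_with: int, bg_n: int
) -> float:
    """Upper-tail hypergeometric P(X >= fg_with): probability of drawing at
    least ``fg_with`` motif-containing sequences in ``fg_n`` draws from the
    pooled fg+bg collection."""
    if not 0 <= fg_with <= fg_n:
        raise ValueError("fg_with must lie in [0, fg_n]")
    if not 0 <= bg_with <= bg_n:
        raise ValueError("bg_with must lie in [0, bg_n]")
    M = fg_n + bg_n          # population size
    K = fg_with + bg_with    # motif-containing sequences in the pool
    return float(stats.hypergeom.sf(fg_with - 1, M, K, fg_n))


def _kmer_presence(sequences: Sequence[str], k: int) -> np.ndarray:
    """ZOOPS presence counts for all 4^k k-mers, as an int array indexed by
    the base-4 encoding of the k-mer (A=0, C=1, G=2, T=3)."""
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    counts = np.zeros(4 ** k, dtype=np.int64)
    for seq in sequences:
        enc = code[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        if len(enc) < k:
            continue
        # rolling base-4 encoding; windows touching a masked char are invalid
        valid = enc >= 0
        idx = np.zeros(len(enc) - k + 1, dtype=np.int64)
        ok = np.ones(len(enc) - k + 1, dtype=bool)
        for j in range(k):
            idx = idx * 4 + np.where(valid[j:j + len(idx)], enc[j:j + len(idx)], 0)
            ok &= valid[j:j + len(idx)]
        present = np.unique(idx[ok])
        counts[present] += 1
    return counts


def _decode(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def markov_shuffle(
    sequences: Sequence[str], rng: np.random.Generator
) -> List[str]:
    """Background sequences resampled per-sequence from a first-order Markov
    chain fitted to that sequence (dinucleotide-frequency-preserving in
    expectation)."""
    out: List[str] = []
    for seq in sequences:
        s = seq.upper()
        if len(s) < 2:
            out.append(s)
            continue
        trans = {b: [] for b in _BASES}
        for a, b in zip(s, s[1:]):
            if a in trans and b in _BASES:
                trans[a].append(b)
        cur = s[0] if s[0] in _BASES else "A"
        chars = [cur]
        for _ in range(len(s) - 1):
            choices = trans.get(cur) or list(_BASES)
            cur = choices[int(rng.integers(len(choices)))]
            chars.append(cur)
        out.append("".join(chars))
    return out


def discover_motifs(
    fg: Sequence[str],
    bg: Optional[Sequence[str]] = None,
    k: int = 8,
    top: int = 10,
    collapse_rc: bool = False,
    seed: int = 0,
) -> List[MotifResult]:
    """Score all 4^k k-mers by ZOOPS counting + hypergeometric enrichment.

    Results are BH-corrected across every tested k-mer and sorted by p-value
    with lexicographic tie-break; the ``top`` best are returned.  Without an
    explicit background, a first-order Markov resample of the foreground is
    used.  ``collapse_rc`` merges each k-mer with its reverse complement
    (counting a sequence once if it contains either).
    """
    if not fg:
        raise ValueError("foreground must be non-empty")
    if k < 1 or k > 12:
        raise ValueError("k must be in [1, 12]")
    if bg is None:
        bg = markov_shuffle(fg, np.random.default_rng(seed))
    if not bg:
        raise ValueError("background must be non-empty")

    fg_counts = _kmer_presence(fg, k)
    bg_counts = _kmer_presence(bg, k)
    if collapse_rc:
        n = 4 ** k
        rc = np.empty(n, dtype=np.int64)
        for idx in range(n):
            kmer = _decode(idx, k)
            rc_kmer = kmer.translate(_COMPLEMENT)[::-1]
            rc[idx] = int(rc_kmer.replace("A", "0").replace("C", "1")
                          .replace("G", "2").replace("T", "3"), 4)
        # union-of-hits upper bound is not exact ZOOPS; recount pairwise
        keep = np.arange(n) <= rc
        fg_rc = np.zeros(n, dtype=np.int64)
        bg_rc = np.zeros(n, dtype=np.int64)
        for idx in np.nonzero(keep)[0]:
            kmer = _decode(int(idx), k)
            pair = {kmer, kmer.translate(_COMPLEMENT)[::-1]}
            fg_rc[idx] = sum(
                1 for s in fg if any(p in s.upper() for p in pair)
            )
            bg_rc[idx] = sum(
                1 for s in bg if any(p in s.upper() for p in pair)
            )
        fg_counts, bg_counts = fg_rc, bg_rc
        tested = np.nonzero(keep)[0]
    else:
        tested = np.arange(4 ** k)

    fg_n, bg_n = len(fg), len(bg)
    M = fg_n + bg_n
    K = fg_counts[tested] + bg_counts[tested]
    pvals = stats.hypergeom.sf(fg_counts[tested] - 1, M, K, fg_n)
    qvals = bh_adjust(pvals)
    order = sorted(
        range(len(tested)), key=lambda i: (pvals[i], _decode(int(tested[i]), k))
    )
    results = [
        MotifResult(
            kmer=_decode(int(tested[i]), k),
            fg_with=int(fg_counts[tested[i]]),
            bg_with=int(bg_counts[tested[i]]),
            fg_n=fg_n,
            bg_n=bg_n,
            pvalue=float(pvals[i]),
            qvalue=float(qvals[i]),
        )
        for i in order[:top]
    ]
    return results


def random_sequences(
    n: int, length: int, rng: np.random.Generator
) -> List[str]:
    """Uniform-composition random DNA sequences (test/background helper)."""
    return [
        "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        for _ in range(n)
    ]


def plant_motif(
    sequences: Sequence[str],
    motif: str,
    fraction: float,
    rng: np.random.Generator,
) -> List[str]:
    """Overwrite a random position of a random subset of sequences with
    ``motif`` (one occurrence per chosen sequence)."""
    out = list(sequences)
    n_plant = int(round(fraction * len(out)))
    chosen = rng.choice(len(out), size=n_plant, replace=False)
    for i in chosen:
        s = out[i]
        if len(s) < len(motif):
            continue
        pos = int(rng.integers(0, len(s) - len(motif) + 1))
        out[i] = s[:pos] + motif + s[pos + len(motif):]
    return out
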