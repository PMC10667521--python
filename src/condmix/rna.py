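"""RNA-RNA complementary-site search with Watson-Crick and G-U wobble pairing.

A complementary site is a maximal, perfectly paired antiparallel duplex:
position i + t of the first sequence pairs with position (end2 - 1 - t) of
the second, every aligned pair drawn from {G:C, C:G, A:U, U:A} plus the
wobble pairs {G:U, U:G} when enabled.  Only duplexes of at least
``min_length`` nucleotides (default 11) are reported, and sub-runs of a
longer maximal run are suppressed.  Coordinates are 0-based half-open
internally; reports add 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
VALID = set("ACGU")


def encode_rna(seq: str) -> np.ndarray:
    """Validate and encode an RNA string (T is auto-converted to U)."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - VALID
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return np.fromiter((_CODE[c] for c in s), dtype=np.int8, count=len(s))


def _pair_table(wobble: bool) -> np.ndarray:
    ok = np.zeros((4, 4), dtype=bool)
    ok[_CODE["G"], _CODE["C"]] = ok[_CODE["C"], _CODE["G"]] = True
    ok[_CODE["A"], _CODE["U"]] = ok[_CODE["U"], _CODE["A"]] = True
    if wobble:
        ok[_CODE["G"], _CODE["U"]] = ok[_CODE["U"], _CODE["G"]] = True
    return ok


@dataclass(frozen=True)
class ComplementaryMatch:
    """One maximal antiparallel duplex between two sequences."""

    start1: int
    end1: int    # half-open
    start2: int
    end2: int    # half-open
    length: int

    def report_coords(self):
        """1-based inclusive coordinates for human-readable output."""
        return (self.start1 + 1, self.end1, self.start2 + 1, self.end2)


def find_complementary_sites(seq1: str, seq2: str,
                             min_length: int = 11,
                             wobble: bool = True) -> list[ComplementaryMatch]:
    """All maximal perfectly paired antiparallel duplexes of length >= min_length.

    Self-comparison (seq1 == seq2) is supported for homotypic sites.
    Matches are ordered deterministically by (start1, start2).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    s1 = encode_rna(seq1)
    s2 = encode_rna(seq2)
    if len(s1) == 0 or len(s2) == 0:
        return []
    ok = _pair_table(wobble)
    r2 = s2[::-1]
    n1, n2 = len(s1), len(r2)
    # match[i, m] true when s1[i] can pair with s2 position (n2 - 1 - m)
    match = ok[s1[:, None], r2[None, :]]

    out = []
    # scan runs along every diagonal of the match matrix
    for off in range(-(n1 - 1), n2):
        diag = np.diagonal(match, offset=off)
        if len(diag) < min_length:
            continue
        padded = np.concatenate([[False], diag, [False]]).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            length = b - a
            if length < min_length:
                continue
            i = a if off >= 0 else a - off
            m = a + off if off >= 0 else a
            # reversed-seq2 window [m, m+length) maps back to seq2 coords
            start2 = n2 - (m + length)
            out.append(ComplementaryMatch(
                start1=int(i), end1=int(i + length),
                start2=int(start2), end2=int(start2 + length),
                length=int(length)))
    out.sort(key=lambda m: (m.start1, m.start2))
    return out


def mean_site_reactivity(matches: list[ComplementaryMatch],
                         reactivity1,
                         reactivity2=None):
    """Mean per-nucleotide reactivity over all matched positions.

    ``reactivity1`` maps positions of the first sequence to reactivity
    values (array or dict); ``reactivity2`` optionally covers the second
    sequence.  Each matched nucleotide position counts once; positions
    with missing (NaN or absent) values are skipped and their count is
    returned alongside the mean.

    Returns (mean, n_used, n_missing).
    """
    if not matches:
        raise ValueError("no matches: mean reactivity undefined")

    def lookup(table, pos):
        if table is None:
            return None
        if isinstance(table, dict):
            return table.get(pos)
        if 0 <= pos < len(table):
            return table[pos]
        return None

    cover1 = sorted({p for m in matches for p in range(m.start1, m.end1)})
    cover2 = sorted({p for m in matches for p in range(m.start2, m.end2)}) \
        if reactivity2 is not None else []
    values, missing = [], 0
    for pos in cover1:
        v = lookup(reactivity1, pos)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing += 1
        else:
            values.append(float(v))
    for pos in cover2:
        v = lookup(reactivity2, pos)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            missing += 1
        else:
            values.append(float(v))
    if not values:
        raise ValueError("no matched nucleotides with defined reactivity")
    return float(np.mean(values)), len(values), missing
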