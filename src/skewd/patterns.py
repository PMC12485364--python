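"""Site-pattern classification and counting from four-taxon alignments.

Patterns are the parsimony-informative biallelic arrangements over
(P1, P2, P3, O) with the outgroup state labelled A:

    ABBA:  s(P1) = s(O)  != s(P2) = s(P3)
    BABA:  s(P1) = s(P3) != s(P2) = s(O)
    BBAA:  s(P1) = s(P2) != s(P3) = s(O)

Everything else (invariant sites, singletons, three or more alleles, and any
site containing a non-ACGT symbol) is OTHER.  Counts are partitioned into
contiguous equal-length blocks, the resampling unit of the block jackknife.
Block intervals are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = ["PATTERNS", "BlockCounts", "classify_site", "count_patterns", "read_alignment"]

PATTERNS = ("ABBA", "BABA", "BBAA")


@dataclass
class BlockCounts:
    """Pattern counts per contiguous genome block.

    counts has shape (n_blocks, 3) in PATTERNS order; starts/ends are 0-based
    half-open bp intervals; total_sites is the alignment length.
    """

    counts: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    total_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_blocks, 3)")
        if np.any(self.counts < 0):
            raise ValueError("negative pattern count")

    @property
    def n_blocks(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def classify_site(states) -> str:
    """Classify one alignment column, given as four single characters (or a
    4-string) ordered P1, P2, P3, O."""
    s = [str(x).upper() for x in states]
    if len(s) != 4 or any(len(x) != 1 for x in s):
        raise ValueError("a site is exactly four single-character states")
    if any(x not in "ACGT" for x in s):
        return "OTHER"
    a, b, c, d = s
    if a == d and b == c and a != b:
        return "ABBA"
    if a == c and b == d and a != b:
        return "BABA"
    if a == b and c == d and a != c:
        return "BBAA"
    return "OTHER"


def read_alignment(path: str) -> dict[str, np.ndarray]:
    """Read a multi-FASTA alignment into {name: uint8 byte array}."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        out[rec.id] = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
    if not out:
        raise ValueError(f"no sequences in {path}")
    lens = {v.size for v in out.values()}
    if len(lens) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return out


def count_patterns(
    alignment: dict[str, np.ndarray | str],
    taxa: tuple[str, str, str, str] = ("P1", "P2", "P3", "O"),
    n_blocks: int = 100,
    block_bp: int | None = None,
) -> BlockCounts:
    """Count ABBA/BABA/BBAA per contiguous block.

    ``taxa`` maps alignment names onto the roles (P1, P2, P3, outgroup last).
    Blocks are equal-length; give either a block count or a block size in bp.
    """
    try:
        rows = [alignment[t] for t in taxa]
    except KeyError as e:
        raise KeyError(f"taxon {e} missing from alignment") from None
    rows = [
        np.frombuffer(r.upper().encode(), dtype=np.uint8) if isinstance(r, str) else r
        for r in rows
    ]
    if len({r.size for r in rows}) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    s0, s1, s2, s3 = rows
    n = s0.size
    valid = np.ones(n, dtype=bool)
    for r in rows:
        ok = np.zeros(256, dtype=bool)
        ok[[ord(c) for c in "ACGT"]] = True
        valid &= ok[r]
    abba = valid & (s0 == s3) & (s1 == s2) & (s0 != s1)
    baba = valid & (s0 == s2) & (s1 == s3) & (s0 != s1)
    bbaa = valid & (s0 == s1) & (s2 == s3) & (s0 != s2)

    if block_bp is not None:
        edges = np.arange(0, n + block_bp, block_bp).astype(np.intp)
        edges[-1] = n
        edges = np.unique(edges)
    else:
        if n_blocks < 1 or n_blocks > n:
            raise ValueError("invalid block count")
        edges = np.linspace(0, n, n_blocks + 1).astype(np.intp)
    per_site = np.stack([abba, baba, bbaa], axis=1).astype(np.int64)
    counts = np.add.reduceat(per_site, edges[:-1], axis=0)
    return BlockCounts(
        counts=counts, starts=edges[:-1], ends=edges[1:], total_sites=n
    )
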