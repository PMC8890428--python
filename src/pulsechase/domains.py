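"""Structure-function mapping of a degradation domain.

Two small pieces of sequence logic used to localize a degron:

* combine deletion-construct phenotypes (which deletions delay degradation,
  which leave it normal) into a candidate residue interval — the region must
  lie inside every delayed deletion and outside every normal one; and
* scan two protein sequences for short ungapped windows of high identity
  (a fixed-length conserved-window scan, no gaps, exact-match identity).

All residue coordinates are 1-based inclusive, matching construct names of
the form "Twine60-135" (deletion of residues 60 through 135 inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeletionConstruct",
    "RegionCall",
    "ConservedWindow",
    "ChimeraConstruct",
    "localize_required_region",
    "scan_conserved_window",
    "annotate_chimera",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")

NORMAL = "normal_degradation"
DELAYED = "delayed_degradation"


@dataclass(frozen=True)
class DeletionConstruct:
    """A deletion construct: residues [start, end] removed, 1-based inclusive."""

    name: str
    start: int
    end: int
    phenotype: str  # NORMAL | DELAYED
    note: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.name}: need 1 <= start <= end")
        if self.phenotype not in (NORMAL, DELAYED):
            raise ValueError(f"{self.name}: unknown phenotype {self.phenotype!r}")

    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))


@dataclass
class RegionCall:
    """Candidate degradation-required region inferred from deletion phenotypes.

    ``intervals`` is a list of (start, end) 1-based inclusive runs; empty with
    the "inconsistent_or_uninformative" flag when the phenotypes admit no
    residue.  The candidate is contained in every delayed interval and is
    disjoint from every normal interval, by construction (re-asserted).
    """

    intervals: list[tuple[int, int]]
    total_length: int
    supporting: list[str]  # delayed constructs
    excluding: list[str]  # normal constructs
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "intervals": [list(iv) for iv in self.intervals],
            "total_length": self.total_length,
            "supporting": self.supporting,
            "excluding": self.excluding,
            "flag": self.flag,
        }


def _runs(residues: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of a sorted 1-based residue array as (start, end)."""
    if residues.size == 0:
        return []
    breaks = np.nonzero(np.diff(residues) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [residues.size - 1]])
    return [(int(residues[a]), int(residues[b])) for a, b in zip(starts, ends)]


def localize_required_region(constructs: Sequence[DeletionConstruct]) -> RegionCall:
    """Intersect delayed deletions, subtract normal ones, on residue sets.

    Logic: a residue required for degradation must be missing from every
    construct whose degradation is delayed, and present in (i.e. outside the
    deletion of) every construct that degrades normally.
    """
    delayed = [c for c in constructs if c.phenotype == DELAYED]
    normal = [c for c in constructs if c.phenotype == NORMAL]
    if not delayed:
        raise ValueError("need at least one delayed-phenotype construct")
    max_res = max(c.end for c in constructs)
    member = np.ones(max_res + 2, dtype=bool)  # index = residue, 1-based
    member[0] = False
    for c in delayed:
        m = np.zeros_like(member)
        m[c.start:c.end + 1] = True
        member &= m
    for c in normal:
        member[c.start:c.end + 1] = False
    residues = np.nonzero(member)[0]
    intervals = _runs(residues)
    call = RegionCall(
        intervals=intervals,
        total_length=int(residues.size),
        supporting=[c.name for c in delayed],
        excluding=[c.name for c in normal],
        flag=None if intervals else "inconsistent_or_uninformative",
    )
    # re-assert the contract post hoc
    for s, e in call.intervals:
        for c in delayed:
            assert c.start <= s and e <= c.end, "candidate escapes a delayed interval"
        for c in normal:
            assert e < c.start or s > c.end, "candidate overlaps a normal interval"
    return call


# ---------------------------------------------------------------------------
# conserved-window scan


@dataclass(frozen=True)
class ConservedWindow:
    """Ungapped window pair: seq A position i, seq B position j (1-based)."""

    pos_a: int
    pos_b: int
    length: int
    identity: float
    window_a: str
    window_b: str


def _validate_seq(seq: str, L: int, name: str) -> str:
    s = seq.strip().upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")
    if len(s) < L:
        raise ValueError(f"{name}: shorter than window length {L}")
    return s


def scan_conserved_window(
    seq_a: str,
    seq_b: str,
    L: int = 12,
    min_identity: float = 0.8,
) -> list[ConservedWindow]:
    """All ungapped length-L window pairs with identity >= min_identity.

    Identity is the exact-match fraction over the window; the ambiguity
    letter X matches nothing (including another X).  Hits are sorted by
    identity (descending) then by (pos_a, pos_b).
    """
    if L < 1:
        raise ValueError("window length must be >= 1")
    a = _validate_seq(seq_a, L, "seq_a")
    b = _validate_seq(seq_b, L, "seq_b")
    if not 0.0 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0, 1]")

    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    x = ord("X")
    eq = (A[:, None] == B[None, :]) & (A[:, None] != x)
    # window identity = diagonal sums of the match matrix
    na, nb = len(a) - L + 1, len(b) - L + 1
    matches = np.zeros((na, nb), dtype=np.int32)
    for d in range(L):
        matches += eq[d:d + na, d:d + nb]
    ident = matches / L
    ii, jj = np.nonzero(ident >= min_identity - 1e-12)
    hits = [
        ConservedWindow(
            pos_a=int(i) + 1, pos_b=int(j) + 1, length=L,
            identity=float(ident[i, j]),
            window_a=a[i:i + L], window_b=b[j:j + L],
        )
        for i, j in zip(ii, jj)
    ]
    hits.sort(key=lambda w: (-w.identity, w.pos_a, w.pos_b))
    return hits


def windows_to_frame(hits: Iterable[ConservedWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pos_a": h.pos_a, "pos_b": h.pos_b, "length": h.length,
          "identity": h.identity, "window_a": h.window_a, "window_b": h.window_b}
         for h in hits],
        columns=["pos_a", "pos_b", "length", "identity", "window_a", "window_b"])


# ---------------------------------------------------------------------------
# chimera bookkeeping


@dataclass(frozen=True)
class ChimeraConstruct:
    """N-terminus of parent A fused at ``junction`` to the C-terminus of B."""

    junction: int
    sequence: str
    provenance: tuple[tuple[str, int, int], ...]  # (parent, start, end) 1-based

    def __len__(self) -> int:
        return len(self.sequence)


def annotate_chimera(junction: int, parent_a: str, parent_b: str,
                     name_a: str = "A", name_b: str = "B") -> ChimeraConstruct:
    """Compose residues 1..junction of A with junction+1..len(B) of B."""
    a, b = parent_a.strip().upper(), parent_b.strip().upper()
    if not 0 <= junction <= min(len(a), len(b)):
        raise ValueError("junction must lie within both parents' lengths")
    seq = a[:junction] + b[junction:]
    prov = []
    if junction > 0:
        prov.append((name_a, 1, junction))
    if junction < len(b):
        prov.append((name_b, junction + 1, len(b)))
    return ChimeraConstruct(junction=junction, sequence=seq, provenance=tuple(prov))
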