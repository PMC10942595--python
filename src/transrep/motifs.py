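"""Scanner for the Musashi RNA consensus motif RU_nAGU.

The consensus is a purine (R = A or G), a run of one or more U's, then AGU;
the UAG triplet formed by the last U of the run and the following AG is the
minimal core that determines specific recognition.  Sequences are treated as
single-stranded mRNA: T is normalized to U and the reverse complement is
never searched.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["MotifMatch", "scan_consensus", "count_sites", "classify_variant"]

_PURINES = {"A", "G"}
_VALID = {"A", "C", "G", "U"}

#: safety cap on the U-run length (the consensus itself is unbounded above)
DEFAULT_MAX_U_RUN = 10


@dataclass(frozen=True)
class MotifMatch:
    """One consensus occurrence: R U^n A G U at [start, end)."""

    start: int
    end: int
    sequence: str
    r_base: str
    u_run: int

    def __post_init__(self) -> None:
        expected = self.r_base + "U" * self.u_run + "AGU"
        if self.sequence != expected:
            raise ValueError(f"matched text {self.sequence!r} != {expected!r}")

    @property
    def core_slice(self) -> tuple[int, int]:
        """Position range of the UAGU core (last run-U through the final U)."""
        return self.start + self.u_run, self.end


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = [i for i, c in enumerate(s) if c not in _VALID]
    if bad:
        raise ValueError(f"non-nucleotide characters at positions {bad}")
    return s


def scan_consensus(seq: str, max_u_run: int = DEFAULT_MAX_U_RUN) -> list[MotifMatch]:
    """All occurrences of [AG] U{1..max_u_run} AGU in a nucleotide string.

    Overlapping matches at distinct starts are all reported; at a single
    start only the maximal U-run match is kept.
    """
    s = _normalize(seq)
    matches = []
    for start in range(len(s)):
        if s[start] not in _PURINES:
            continue
        best = None
        n = 0
        pos = start + 1
        while pos < len(s) and s[pos] == "U" and n < max_u_run:
            n += 1
            pos += 1
            if s[pos : pos + 3] == "AGU":
                best = n
        if best is not None:
            end = start + 1 + best + 3
            matches.append(MotifMatch(start, end, s[start:end], s[start], best))
    return matches


def count_sites(seq: str, max_u_run: int = DEFAULT_MAX_U_RUN) -> int:
    """Number of consensus occurrences (distinct starts)."""
    return len(scan_consensus(seq, max_u_run))


def classify_variant(
    reference_seq: str,
    variant_seq: str,
    max_u_run: int = DEFAULT_MAX_U_RUN,
) -> list[str]:
    """Classify each reference motif repeat in a point-mutated variant.

    For every consensus match in the reference, the aligned variant
    subsequence is labelled ``intact`` (unchanged), ``core_broken`` (the
    UAGU core mutated — the recognition-determining positions), or
    ``flank_changed`` (only the purine or inner U-run positions differ).
    Indels are unsupported: sequences must be equal length.
    """
    ref = _normalize(reference_seq)
    var = _normalize(variant_seq)
    if len(ref) != len(var):
        raise ValueError("sequences differ in length; point mutations only")
    statuses = []
    for match in scan_consensus(ref, max_u_run):
        core_lo, core_hi = match.core_slice
        if ref[core_lo:core_hi] != var[core_lo:core_hi]:
            statuses.append("core_broken")
        elif ref[match.start : match.end] != var[match.start : match.end]:
            statuses.append("flank_changed")
        else:
            statuses.append("intact")
    return statuses


def brute_force_scan(seq: str, max_u_run: int = DEFAULT_MAX_U_RUN) -> list[MotifMatch]:
    """Reference matcher: test every (start, u_run) pair literally.

    Quadratic and unoptimized on purpose — the independent check for
    ``scan_consensus`` (maximal U-run kept per start).
    """
    s = _normalize(seq)
    found: dict[int, MotifMatch] = {}
    for start in range(len(s)):
        for n in range(1, max_u_run + 1):
            pattern_len = 1 + n + 3
            sub = s[start : start + pattern_len]
            if len(sub) < pattern_len:
                break
            if sub[0] in _PURINES and sub[1 : 1 + n] == "U" * n and sub[1 + n :] == "AGU":
                found[start] = MotifMatch(start, start + pattern_len, sub, sub[0], n)
    return [found[k] for k in sorted(found)]
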