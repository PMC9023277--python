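"""Putative higher-order G-quadruplex motif scanning and strand constants.

A quadruplex-forming motif is modelled as ``tract_count`` runs ("tracts") of
at least ``run_len`` consecutive guanines separated by loops of bounded
length — the classic Quadparser-style query [Gx-Ly-...-Gx], generalised to
8- and 12-tract blocks for stacked (higher-order) quadruplexes.  Tracts are
maximal G-runs: a run longer than ``run_len`` counts as one tract, surplus
guanines are not split into extra tracts (alternative register assignments
are a modelling question, not a scanning one).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InputError, ParameterError

__all__ = [
    "SequenceRecord",
    "G4Motif",
    "count_g_runs",
    "scan_motifs",
    "strand_molecular_weight",
]

# Average masses (Da) of the internal nucleotide residues of a free-acid,
# non-phosphorylated single strand; the constant restores the terminal
# -HPO3 + H2O difference.  MW = sum(residues) - 61.96.
RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}
TERMINAL_CORRECTION = 61.96

_VALID = set("ACGT")


def _normalize_seq(seq: str) -> str:
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _VALID
    if not s:
        raise InputError("empty sequence")
    if bad:
        raise InputError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA strand, normalized to uppercase A/C/G/T."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _normalize_seq(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class G4Motif:
    """A located multi-tract motif, 0-based half-open on the given strand.

    ``strand`` is '+' for G-run motifs on the provided strand and '-' for
    C-run motifs (quadruplexes on the reverse complement), reported in the
    same coordinate system.
    """

    start: int
    end: int
    tract_count: int
    tracts: tuple[tuple[int, int], ...]  # (start, length) per G-run
    loops: tuple[int, ...]  # loop lengths, len == tract_count - 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.loops) != self.tract_count - 1:
            raise ParameterError("loop count must be tract_count - 1")


def count_g_runs(record: SequenceRecord | str, min_len: int, base: str = "G") -> list[tuple[int, int]]:
    """Maximal runs of ``base`` of length >= min_len, ascending, non-overlapping."""
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    seq = record.seq if isinstance(record, SequenceRecord) else _normalize_seq(record)
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(f"{base}+", seq)
        if m.end() - m.start() >= min_len
    ]


def _windows(runs, loop_min, loop_max, tract_count):
    """Qualifying windows of consecutive maximal runs."""
    out = []
    n = len(runs)
    for i in range(n - tract_count + 1):
        ok = True
        loops = []
        for k in range(tract_count - 1):
            s0, l0 = runs[i + k]
            s1, _ = runs[i + k + 1]
            gap = s1 - (s0 + l0)
            if not (loop_min <= gap <= loop_max):
                ok = False
                break
            loops.append(gap)
        if ok:
            out.append((i, tuple(loops)))
    return out


def scan_motifs(
    record: SequenceRecord,
    run_len: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    tract_count: int = 4,
    scan_complement: bool = False,
    mode: str = "leftmost",
) -> list[G4Motif]:
    """Locate putative (higher-order) quadruplex motifs in ``record``.

    ``mode`` accepts "leftmost" (report the leftmost motif, resume scanning
    after its first tract) or "all"; with tracts defined as consecutive
    maximal runs the two enumerate identical windows, so both are accepted.
    When ``scan_complement`` is set, C-run motifs (G4s on the complementary
    strand) are additionally reported with strand '-'.
    """
    if run_len not in (2, 3):
        raise ParameterError("run_len must be 2 or 3")
    if tract_count not in (4, 8, 12):
        raise ParameterError("tract_count must be 4, 8 or 12")
    if loop_min < 1 or loop_max > 10 or loop_min > loop_max:
        raise ParameterError("need 1 <= loop_min <= loop_max <= 10")
    if mode not in ("leftmost", "all"):
        raise ParameterError(f"unknown scan mode {mode!r}")

    motifs: list[G4Motif] = []
    bases = ["G"] + (["C"] if scan_complement else [])
    for base in bases:
        runs = count_g_runs(record, run_len, base=base)
        for i, loops in _windows(runs, loop_min, loop_max, tract_count):
            tracts = tuple(runs[i : i + tract_count])
            start = tracts[0][0]
            end = tracts[-1][0] + tracts[-1][1]
            motifs.append(
                G4Motif(start, end, tract_count, tracts, loops, strand="+" if base == "G" else "-")
            )
    motifs.sort(key=lambda m: (m.start, m.strand))
    return motifs


def strand_molecular_weight(record: SequenceRecord | str) -> float:
    """Average-mass MW (Da) of the free-acid single strand.

    nA*313.21 + nC*289.18 + nG*329.21 + nT*304.2 - 61.96; round to the
    nearest integer for display.
    """
    seq = record.seq if isinstance(record, SequenceRecord) else _normalize_seq(record)
    return sum(RESIDUE_MASS[b] for b in seq) - TERMINAL_CORRECTION
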