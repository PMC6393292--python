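"""Fragment and feature records, BED I/O, and terminus extraction.

Coordinate convention: 0-based, half-open ``[start, end)`` throughout, as in
BED. A fragment's 5' terminus is its first synthesized nucleotide and the 3'
terminus its last, so both termini are *inclusive* positions inside
``[start, end)``:

* ``+`` strand: 5' at ``start``, 3' at ``end - 1``
* ``-`` strand: 5' at ``end - 1``, 3' at ``start``

Strand is mandatory -- synthesis orientation is the point of the analysis --
so records with strand ``.`` are rejected at parse time.

Simulated ground truth about the junction at a fragment's 5' end (ligatable
nick, gap, or unprocessed flap) travels in an optional seventh BED column
with the dialect ``nick``, ``gap:<n>``, ``flap:<n>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-")
JUNCTION_STATES = ("nick", "gap", "flap")
FEATURE_KINDS = ("nucleosome_dyad", "tf_site")
END_KINDS = ("five_prime", "three_prime")


class BedParseError(ValueError):
    """A malformed line in a BED file; the message names the line number."""


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One mapped Okazaki fragment.

    ``junction_state`` describes the junction at the fragment's 5' end and is
    only present for simulated data; ``gap_or_flap_len`` (nt, >= 1) is present
    iff the junction is a gap or a flap.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str = "."
    score: float = 0.0
    junction_state: str | None = None
    gap_or_flap_len: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.junction_state is not None:
            if self.junction_state not in JUNCTION_STATES:
                raise ValueError(f"unknown junction_state {self.junction_state!r}")
            if self.junction_state == "nick":
                if self.gap_or_flap_len is not None:
                    raise ValueError("nick junctions carry no gap/flap length")
            elif self.gap_or_flap_len is None or self.gap_or_flap_len < 1:
                raise ValueError(
                    f"{self.junction_state} junction requires gap_or_flap_len >= 1"
                )
        elif self.gap_or_flap_len is not None:
            raise ValueError("gap_or_flap_len without a junction_state")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class Terminus:
    """A single fragment end: inclusive genomic position plus chemistry."""

    chrom: str
    position: int
    end_kind: str
    strand: str

    def __post_init__(self) -> None:
        if self.end_kind not in END_KINDS:
            raise ValueError(f"end_kind must be one of {END_KINDS}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, slots=True)
class Feature:
    """An oriented point feature (dyad midpoint or TF-site midpoint)."""

    chrom: str
    midpoint: int
    score: float = 0.0
    orientation: str = "none"

    def __post_init__(self) -> None:
        if self.midpoint < 0:
            raise ValueError("midpoint must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.orientation not in ("+", "-", "none"):
            raise ValueError(f"orientation must be +, - or none, got {self.orientation!r}")


@dataclass(frozen=True)
class FeatureSet:
    """A collection of point features of one kind.

    Nucleosome dyads carry occupancy scores (so the "top fraction by
    occupancy" filter is meaningful); TF sites may carry a binding strength.
    Midpoints are unique per (chrom, midpoint).
    """

    kind: str
    records: tuple[Feature, ...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if not isinstance(self.records, tuple):
            object.__setattr__(self, "records", tuple(self.records))
        keys = [(f.chrom, f.midpoint) for f in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, midpoint) in FeatureSet")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.records)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted midpoint array per chromosome (for searchsorted lookups)."""
        out: dict[str, list[int]] = {}
        for f in self.records:
            out.setdefault(f.chrom, []).append(f.midpoint)
        return {c: np.asarray(sorted(ms), dtype=np.int64) for c, ms in out.items()}


# ---------------------------------------------------------------------------
# BED I/O

def _format_junction(rec: FragmentRecord) -> str:
    if rec.junction_state is None:
        return ""
    if rec.junction_state == "nick":
        return "nick"
    return f"{rec.junction_state}:{rec.gap_or_flap_len}"


def _parse_junction(tok: str, lineno: int) -> tuple[str, int | None]:
    if tok == "nick":
        return "nick", None
    for state in ("gap", "flap"):
        if tok.startswith(state + ":"):
            try:
                n = int(tok[len(state) + 1 :])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: bad {state} length in junction field {tok!r}"
                ) from None
            if n < 1:
                raise BedParseError(f"line {lineno}: {state} length must be >= 1")
            return state, n
    raise BedParseError(f"line {lineno}: unrecognized junction field {tok!r}")


def read_fragments(path: str | Path, format: str = "bed6") -> list[FragmentRecord]:
    """Read mapped fragments from a BED6(+1) file.

    The optional seventh column carries the junction dialect
    (``nick`` / ``gap:<n>`` / ``flap:<n>``). Strand ``.`` is rejected:
    without a strand the synthesis orientation of the termini is undefined.
    """
    if format != "bed6":
        raise ValueError(f"unsupported fragment format {format!r}")
    records: list[FragmentRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise BedParseError(
                    f"line {lineno}: expected >= 6 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                score = float(cols[4])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
            strand = cols[5]
            if strand not in STRANDS:
                raise BedParseError(
                    f"line {lineno}: strand must be '+' or '-', got {strand!r}"
                    " (strand is mandatory for terminus assignment)"
                )
            junction_state = flen = None
            if len(cols) >= 7 and cols[6]:
                junction_state, flen = _parse_junction(cols[6], lineno)
            try:
                records.append(
                    FragmentRecord(
                        chrom=cols[0], start=start, end=end, strand=strand,
                        name=cols[3], score=score,
                        junction_state=junction_state, gap_or_flap_len=flen,
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
    return records


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> None:
    """Write fragments as BED6, plus the junction column when present."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            cols = [rec.chrom, str(rec.start), str(rec.end), rec.name,
                    f"{rec.score:g}", rec.strand]
            junction = _format_junction(rec)
            if junction:
                cols.append(junction)
            fh.write("\t".join(cols) + "\n")


def read_features(path: str | Path, kind: str) -> FeatureSet:
    """Read point features from BED.

    Midpoints are taken as ``(start + end) // 2``, which covers both the
    1-bp-interval encoding ``[m, m+1)`` and wider intervals. Scores come from
    BED column 5 (required for nucleosome dyads, where they are occupancies);
    orientation from column 6 when it is ``+`` or ``-``, else ``none``.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"kind must be one of {FEATURE_KINDS}")
    feats: list[Feature] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
            if end <= start:
                raise BedParseError(f"line {lineno}: empty interval [{start}, {end})")
            score = 0.0
            if len(cols) >= 5 and cols[4] not in ("", "."):
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: bad score: {exc}") from None
            elif kind == "nucleosome_dyad":
                raise BedParseError(
                    f"line {lineno}: nucleosome dyads require an occupancy score"
                    " in column 5"
                )
            orientation = "none"
            if len(cols) >= 6 and cols[5] in STRANDS:
                orientation = cols[5]
            feats.append(Feature(cols[0], (start + end) // 2, score, orientation))
    return FeatureSet(kind=kind, records=tuple(feats))


def write_features(features: FeatureSet, path: str | Path) -> None:
    """Write features as BED6 with 1-bp intervals ``[m, m+1)``."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for i, f in enumerate(features):
            strand = f.orientation if f.orientation in STRANDS else "."
            fh.write(
                "\t".join([f.chrom, str(f.midpoint), str(f.midpoint + 1),
                           f"{features.kind[:4]}{i}", f"{f.score:g}", strand]) + "\n"
            )


# ---------------------------------------------------------------------------
# Terminus extraction

def fragment_termini(fragment: FragmentRecord) -> tuple[Terminus, Terminus]:
    """Map a fragment's genomic ends to its chemical (5', 3') termini.

    Synthesis runs 5'->3', so on ``+`` the 5' end is the leftmost base and
    the 3' end the rightmost (``end - 1``); on ``-`` the assignment mirrors.
    Returns ``(five_prime, three_prime)``.
    """
    if fragment.strand == "+":
        p5, p3 = fragment.start, fragment.end - 1
    else:
        p5, p3 = fragment.end - 1, fragment.start
    return (
        Terminus(fragment.chrom, p5, "five_prime", fragment.strand),
        Terminus(fragment.chrom, p3, "three_prime", fragment.strand),
    )


# ---------------------------------------------------------------------------
# Mirroring helpers (orientation-invariance checks)

def mirror_fragment(fragment: FragmentRecord, chrom_length: int) -> FragmentRecord:
    """Reflect a fragment through the chromosome midpoint and flip its strand.

    Under ``p -> L - 1 - p`` the interval ``[start, end)`` maps to
    ``[L - end, L - start)`` and 5'/3' termini swap genomic sides, so a
    mirrored fragment has the same chemistry read in the opposite direction.
    """
    if fragment.end > chrom_length:
        raise ValueError("fragment extends past chrom_length")
    return replace(
        fragment,
        start=chrom_length - fragment.end,
        end=chrom_length - fragment.start,
        strand="-" if fragment.strand == "+" else "+",
    )


def mirror_feature_set(features: FeatureSet, chrom_lengths: Mapping[str, int]) -> FeatureSet:
    """Reflect every feature midpoint through its chromosome midpoint."""
    out = []
    for f in features:
        length = chrom_lengths[f.chrom]
        orientation = f.orientation
        if orientation in STRANDS:
            orientation = "-" if orientation == "+" else "+"
        out.append(replace(f, midpoint=length - 1 - f.midpoint, orientation=orientation))
    return FeatureSet(kind=features.kind, records=tuple(out))
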