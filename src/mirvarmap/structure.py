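"""Pre-miRNA substructure annotation.

A precursor hairpin (pre-mir) is decomposed, strand-aware, into labeled
functional regions: for each annotated mature arm the *seed* (mature
positions 2-8, the primary determinant of target recognition) and the
*rest of mature* ("rom": position 1 and positions 9..end); the *loop*
between the two arms; and the precursor flanks outside the arms
("5' mir" / "3' mir").  Flank regions on a side lacking an annotated
mature product carry a "(mix)" qualifier, since such a region mixes the
putative star strand with true flank sequence.

All coordinates are 1-based inclusive, matching both GFF3 and VCF.
Region order is always reported in transcribed 5'->3' orientation, so a
minus-strand precursor yields the same label sequence as its plus-strand
mirror image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gffutils

logger = logging.getLogger(__name__)

# Canonical region label values (transcribed-strand vocabulary).
SEED_5P = "5' seed miR"
ROM_5P = "5' rom miR"
SEED_3P = "3' seed miR"
ROM_3P = "3' rom miR"
LOOP = "loop"
MIR_5P = "5' mir"
MIR_3P = "3' mir"

REGION_VALUES = (SEED_5P, ROM_5P, SEED_3P, ROM_3P, LOOP, MIR_5P, MIR_3P)

#: mature-seed span in mature-local coordinates (1-based, inclusive)
SEED_FIRST, SEED_LAST = 2, 8


class GFFParseError(ValueError):
    """Malformed annotation line (reported with its line number)."""


class StructureValidationError(ValueError):
    """Annotation violates a structural invariant (e.g. mature outside precursor)."""


class PositionOutsidePrecursor(LookupError):
    """Queried position does not fall inside the precursor; caller should skip."""


@dataclass(frozen=True)
class GenomicInterval:
    """Closed genomic interval, 1-based on a stranded sequence."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise StructureValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class RegionLabel:
    """One of the seven substructure labels, optionally qualified "(mix)"."""

    value: str
    mix: bool = False

    def __post_init__(self) -> None:
        if self.value not in REGION_VALUES:
            raise StructureValidationError(f"unknown region label {self.value!r}")

    def __str__(self) -> str:
        return f"{self.value} (mix)" if self.mix else self.value

    @property
    def is_seed(self) -> bool:
        return self.value in (SEED_5P, SEED_3P)

    @property
    def is_mature(self) -> bool:
        return self.value in (SEED_5P, SEED_3P, ROM_5P, ROM_3P)


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    interval: GenomicInterval
    arm: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise StructureValidationError(f"{self.id}: arm must be '5p' or '3p', got {self.arm!r}")


@dataclass(frozen=True)
class PreMiRNA:
    id: str
    interval: GenomicInterval
    mature_arms: tuple[MatureMiRNA, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mature_arms) > 2:
            raise StructureValidationError(f"{self.id}: more than two mature arms")
        for m in self.mature_arms:
            if not self.interval.contains_interval(m.interval):
                raise StructureValidationError(
                    f"mature {m.id} ({m.interval.chrom}:{m.interval.start}-{m.interval.end}) "
                    f"extends outside precursor {self.id} "
                    f"({self.interval.chrom}:{self.interval.start}-{self.interval.end})"
                )
        if len(self.mature_arms) == 2:
            a, b = self.mature_arms
            if a.interval.overlaps(b.interval):
                raise StructureValidationError(
                    f"mature arms {a.id} and {b.id} of {self.id} overlap"
                )

    def to_transcribed(self, pos: int) -> int:
        """Genomic position -> 1-based position along the transcribed strand."""
        if not self.interval.contains(pos):
            raise PositionOutsidePrecursor(f"{pos} outside {self.id}")
        if self.interval.strand == "+":
            return pos - self.interval.start + 1
        return self.interval.end - pos + 1

    def to_genomic(self, t_start: int, t_end: int) -> GenomicInterval:
        """Transcribed-coordinate span (t_start <= t_end) -> genomic interval."""
        iv = self.interval
        if iv.strand == "+":
            return GenomicInterval(iv.chrom, iv.start + t_start - 1, iv.start + t_end - 1, "+")
        return GenomicInterval(iv.chrom, iv.end - t_end + 1, iv.end - t_start + 1, "-")


@dataclass(frozen=True)
class Segment:
    label: RegionLabel
    interval: GenomicInterval
    mature_id: Optional[str] = None  # set for seed/rom segments


@dataclass
class SubstructureMap:
    """Ordered (transcribed 5'->3') partition of a precursor into labeled segments."""

    premirna_id: str
    precursor: GenomicInterval
    segments: list[Segment] = field(default_factory=list)

    def locate(self, pos: int) -> RegionLabel:
        """Label of the segment containing the genomic position ``pos``."""
        seg = self.locate_segment(pos)
        return seg.label

    def locate_segment(self, pos: int) -> Segment:
        if not self.precursor.contains(pos):
            raise PositionOutsidePrecursor(
                f"position {pos} outside precursor {self.premirna_id}"
            )
        for seg in self.segments:
            if seg.interval.contains(pos):
                return seg
        raise AssertionError(  # pragma: no cover - partition invariant
            f"{self.premirna_id}: position {pos} in precursor but in no segment"
        )

    def validate_partition(self) -> None:
        """Segments must be disjoint and tile the precursor exactly."""
        total = sum(s.interval.length for s in self.segments)
        if total != self.precursor.length:
            raise StructureValidationError(
                f"{self.premirna_id}: segment lengths sum to {total}, "
                f"precursor length is {self.precursor.length}"
            )
        spans = sorted((s.interval.start, s.interval.end) for s in self.segments)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise StructureValidationError(f"{self.premirna_id}: overlapping segments")

    def iter_base_labels(self) -> Iterator[tuple[int, RegionLabel]]:
        """Yield (genomic position, label) for every base of the precursor."""
        for seg in self.segments:
            for pos in range(seg.interval.start, seg.interval.end + 1):
                yield pos, seg.label


def _arm_segments(pre: PreMiRNA, mature: MatureMiRNA, side: str) -> list[tuple[RegionLabel, int, int, str]]:
    """Split one mature arm into rom/seed/rom in transcribed coordinates.

    Returns (label, t_start, t_end, mature_id) tuples.  Seed is mature
    positions 2-8; position 1 and 9..L are rest-of-mature.  Arms shorter
    than 8 nt get a truncated seed (positions 2..L) with a warning.
    """
    a = pre.to_transcribed(mature.interval.start)
    b = pre.to_transcribed(mature.interval.end)
    a, b = min(a, b), max(a, b)
    length = b - a + 1
    seed_lab = RegionLabel(SEED_5P if side == "5p" else SEED_3P)
    rom_lab = RegionLabel(ROM_5P if side == "5p" else ROM_3P)
    out: list[tuple[RegionLabel, int, int, str]] = [(rom_lab, a, a, mature.id)]
    if length >= SEED_FIRST:
        seed_end = min(a + SEED_LAST - 1, b)
        if length < SEED_LAST:
            warnings.warn(
                f"mature {mature.id} is {length} nt (<{SEED_LAST}); "
                f"seed truncated to positions {SEED_FIRST}..{length}",
                stacklevel=3,
            )
        out.append((seed_lab, a + SEED_FIRST - 1, seed_end, mature.id))
        if b > seed_end:
            out.append((rom_lab, seed_end + 1, b, mature.id))
    return out


def decompose(pre: PreMiRNA) -> SubstructureMap:
    """Decompose a precursor into its substructure partition.

    With two arms: 5' mir flank, 5p arm (rom/seed/rom), loop, 3p arm
    (rom/seed/rom), 3' mir flank.  With one arm the opposite flank is
    "(mix)".  With no arms the precursor splits at the transcribed
    midpoint into "5' mir (mix)" and "3' mir (mix)".  Zero-length
    flanks/loops are omitted.
    """
    L = pre.interval.length
    parts: list[tuple[RegionLabel, int, int, Optional[str]]] = []

    # order arms by transcribed start (arms never overlap)
    arms = sorted(
        pre.mature_arms,
        key=lambda m: min(pre.to_transcribed(m.interval.start), pre.to_transcribed(m.interval.end)),
    )

    if not arms:
        mid = (L + 1) // 2
        parts.append((RegionLabel(MIR_5P, mix=True), 1, mid, None))
        if mid < L:
            parts.append((RegionLabel(MIR_3P, mix=True), mid + 1, L, None))
    else:
        arm_by_side = {m.arm: m for m in arms}
        if len(arms) == 2 and len(arm_by_side) != 2:
            raise StructureValidationError(
                f"{pre.id}: both mature arms claim the same side ({arms[0].arm})"
            )
        spans = {
            m.arm: (
                min(pre.to_transcribed(m.interval.start), pre.to_transcribed(m.interval.end)),
                max(pre.to_transcribed(m.interval.start), pre.to_transcribed(m.interval.end)),
            )
            for m in arms
        }
        if "5p" in spans and "3p" in spans and spans["5p"][0] > spans["3p"][0]:
            raise StructureValidationError(
                f"{pre.id}: 5p arm lies downstream of 3p arm in transcribed order"
            )

        first = arms[0]
        last = arms[-1]
        t_first = spans[first.arm][0]
        t_last_end = spans[last.arm][1]

        if t_first > 1:
            parts.append((RegionLabel(MIR_5P, mix="5p" not in arm_by_side), 1, t_first - 1, None))
        cursor = None
        for m in arms:
            lo, hi = spans[m.arm]
            if cursor is not None and lo > cursor + 1:
                parts.append((RegionLabel(LOOP), cursor + 1, lo - 1, None))
            for lab, s, e, mid_id in _arm_segments(pre, m, m.arm):
                parts.append((lab, s, e, mid_id))
            cursor = hi
        if t_last_end < L:
            parts.append((RegionLabel(MIR_3P, mix="3p" not in arm_by_side), t_last_end + 1, L, None))

    segs = [
        Segment(label=lab, interval=pre.to_genomic(s, e), mature_id=mid_id)
        for lab, s, e, mid_id in parts
    ]
    smap = SubstructureMap(premirna_id=pre.id, precursor=pre.interval, segments=segs)
    smap.validate_partition()
    return smap


def infer_arm(pre_interval: GenomicInterval, mature_interval: GenomicInterval) -> str:
    """Assign 5p/3p by the transcribed-orientation midpoint rule."""
    if pre_interval.strand == "+":
        t_center = (mature_interval.start + mature_interval.end) / 2 - pre_interval.start + 1
    else:
        t_center = pre_interval.end - (mature_interval.start + mature_interval.end) / 2 + 1
    return "5p" if t_center <= (pre_interval.length + 1) / 2 else "3p"


def _arm_from_name(name: str) -> Optional[str]:
    lowered = name.lower()
    if lowered.endswith("-5p"):
        return "5p"
    if lowered.endswith("-3p"):
        return "3p"
    return None


def _prescan_gff(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFFParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if start > end:
                raise GFFParseError(f"{path}:{lineno}: start {start} > end {end}")
            if fields[6] not in ("+", "-"):
                raise GFFParseError(f"{path}:{lineno}: strand must be + or -, got {fields[6]!r}")


def parse_mirna_gff(path: str | Path) -> list[PreMiRNA]:
    """Read a miRBase-dialect GFF3 into PreMiRNA records.

    Expects ``miRNA_primary_transcript`` features for precursors and
    ``miRNA`` features for mature products, linked by ``Derives_from``.
    Coordinates are kept 1-based inclusive.  Arm side comes from the
    mature Name suffix (-5p/-3p) when present, else from the midpoint
    rule.
    """
    path = Path(path)
    _prescan_gff(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    precursors: dict[str, dict] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        pid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [pid])[0]
        precursors[pid] = {
            "name": name,
            "interval": GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand),
            "matures": [],
        }

    for feat in db.features_of_type("miRNA"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        parents = feat.attributes.get("Derives_from", [])
        if not parents:
            raise StructureValidationError(f"mature record {name} has no Derives_from parent")
        parent = parents[0]
        if parent not in precursors:
            raise StructureValidationError(
                f"mature record {name} derives from unknown precursor {parent}"
            )
        entry = precursors[parent]
        m_iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        if not entry["interval"].contains_interval(m_iv):
            raise StructureValidationError(
                f"mature {name} ({m_iv.chrom}:{m_iv.start}-{m_iv.end}) extends outside "
                f"precursor {entry['name']} "
                f"({entry['interval'].chrom}:{entry['interval'].start}-{entry['interval'].end})"
            )
        arm = _arm_from_name(name) or infer_arm(entry["interval"], m_iv)
        entry["matures"].append(MatureMiRNA(id=name, interval=m_iv, arm=arm))

    out = []
    for entry in precursors.values():
        out.append(
            PreMiRNA(
                id=entry["name"],
                interval=entry["interval"],
                mature_arms=tuple(
                    sorted(entry["matures"], key=lambda m: m.interval.start)
                ),
            )
        )
    logger.info("parsed %d precursors from %s", len(out), path)
    return out


def build_substructure_maps(premirnas: Sequence[PreMiRNA]) -> dict[str, SubstructureMap]:
    return {pre.id: decompose(pre) for pre in premirnas}


def write_substructure_bed(maps: Sequence[SubstructureMap] | dict[str, SubstructureMap],
                           path: str | Path) -> None:
    """Export segments as BED6 (0-based half-open, as BED requires)."""
    if isinstance(maps, dict):
        maps = list(maps.values())
    with open(path, "w") as fh:
        for smap in maps:
            for seg in smap.segments:
                iv = seg.interval
                name = f"{smap.premirna_id}|{seg.label}"
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
                )
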