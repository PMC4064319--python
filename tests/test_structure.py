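"""Substructure decomposition: partition, strand symmetry, per-base oracle."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirvarmap.structure import (
    LOOP, MIR_3P, MIR_5P, ROM_3P, ROM_5P, SEED_3P, SEED_5P,
    GenomicInterval, GFFParseError, MatureMiRNA, PositionOutsidePrecursor,
    PreMiRNA, StructureValidationError, decompose, parse_mirna_gff,
    write_substructure_bed,
)


def oracle_base_labels(L, arm5=None, arm3=None):
    """Independent per-base labeling in transcribed coordinates.

    ``arm5``/``arm3`` are (t_start, t_end) spans or None.  Returns a list
    of (value, mix) per transcribed position 1..L, by direct rule lookup.
    """
    out = []
    for t in range(1, L + 1):
        if arm5 is None and arm3 is None:
            mid = (L + 1) // 2
            out.append((MIR_5P, True) if t <= mid else ((MIR_3P, True)))
            continue
        placed = None
        for span, seed_v, rom_v in ((arm5, SEED_5P, ROM_5P), (arm3, SEED_3P, ROM_3P)):
            if span and span[0] <= t <= span[1]:
                local = t - span[0] + 1
                placed = (seed_v, False) if 2 <= local <= 8 else (rom_v, False)
        if placed:
            out.append(placed)
        elif arm5 and t < arm5[0]:
            out.append((MIR_5P, False))
        elif arm3 and t > arm3[1]:
            out.append((MIR_3P, False))
        elif arm5 and arm3 and arm5[1] < t < arm3[0]:
            out.append((LOOP, False))
        elif arm5 and t > arm5[1]:  # no 3p arm annotated
            out.append((MIR_3P, True))
        else:  # no 5p arm annotated
            out.append((MIR_5P, True))
    return out


def build_pre(start, L, strand, arm5=None, arm3=None, chrom="1"):
    """PreMiRNA from transcribed-coordinate arm spans."""
    iv = GenomicInterval(chrom, start, start + L - 1, strand)
    helper = PreMiRNA(id="pre", interval=iv)
    arms = []
    for span, side in ((arm5, "5p"), (arm3, "3p")):
        if span:
            g = helper.to_genomic(*span)
            arms.append(MatureMiRNA(id=f"mat-{side}", interval=g, arm=side))
    return PreMiRNA(id="pre", interval=iv, mature_arms=tuple(sorted(arms, key=lambda m: m.interval.start)))


def transcribed_labels(pre):
    smap = decompose(pre)
    labels = {}
    for pos, lab in smap.iter_base_labels():
        labels[pre.to_transcribed(pos)] = (lab.value, lab.mix)
    return [labels[t] for t in range(1, pre.interval.length + 1)]


class TestDecompose:
    def test_two_arm_example_nine_segments(self):
        """Worked example: precursor 1-80 with arms at 5-26 and 50-71."""
        pre = build_pre(1, 80, "+", arm5=(5, 26), arm3=(50, 71))
        smap = decompose(pre)
        got = [(s.label.value, s.interval.start, s.interval.end) for s in smap.segments]
        assert got == [
            (MIR_5P, 1, 4),
            (ROM_5P, 5, 5),
            (SEED_5P, 6, 12),
            (ROM_5P, 13, 26),
            (LOOP, 27, 49),
            (ROM_3P, 50, 50),
            (SEED_3P, 51, 57),
            (ROM_3P, 58, 71),
            (MIR_3P, 72, 80),
        ]
        assert sum(s.interval.length for s in smap.segments) == 80

    def test_minus_strand_mirror_same_label_sequence(self):
        plus = build_pre(1, 80, "+", arm5=(5, 26), arm3=(50, 71))
        minus = build_pre(1, 80, "-", arm5=(5, 26), arm3=(50, 71))
        assert transcribed_labels(plus) == transcribed_labels(minus)

    def test_no_arm_precursor_splits_at_midpoint_with_mix(self):
        pre = build_pre(100, 81, "+")
        smap = decompose(pre)
        assert [(s.label.value, s.label.mix) for s in smap.segments] == [
            (MIR_5P, True), (MIR_3P, True),
        ]
        assert smap.segments[0].interval.length == 41  # ceil(81/2)
        assert smap.segments[1].interval.length == 40

    def test_single_arm_marks_opposite_flank_mix(self):
        pre = build_pre(1, 80, "+", arm5=(10, 31))
        smap = decompose(pre)
        values = [(s.label.value, s.label.mix) for s in smap.segments]
        assert values[0] == (MIR_5P, False)
        assert values[-1] == (MIR_3P, True)
        assert LOOP not in [v for v, _ in values]

    def test_short_arm_truncates_seed_with_warning(self):
        pre = build_pre(1, 60, "+", arm5=(10, 14))  # 5 nt arm
        with pytest.warns(UserWarning, match="seed truncated"):
            smap = decompose(pre)
        seed = [s for s in smap.segments if s.label.value == SEED_5P]
        assert len(seed) == 1 and seed[0].interval.length == 4  # positions 2..5

    def test_abutting_arms_have_no_loop(self):
        pre = build_pre(1, 60, "+", arm5=(5, 24), arm3=(25, 44))
        smap = decompose(pre)
        assert LOOP not in [s.label.value for s in smap.segments]
        smap.validate_partition()

    def test_overlapping_arms_rejected(self):
        with pytest.raises(StructureValidationError, match="overlap"):
            build_pre(1, 80, "+", arm5=(5, 30), arm3=(25, 50))


class TestLocate:
    def test_seed_starts_at_mature_position_two(self):
        pre = build_pre(1, 80, "+", arm5=(5, 26), arm3=(50, 71))
        smap = decompose(pre)
        assert smap.locate(6).value == SEED_5P  # mature position 2
        assert smap.locate(5).value == ROM_5P  # mature position 1 excluded from seed

    def test_outside_position_raises(self):
        smap = decompose(build_pre(10, 50, "+", arm5=(5, 26)))
        with pytest.raises(PositionOutsidePrecursor):
            smap.locate(5)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_every_base_matches_oracle(self, strand):
        pre = build_pre(200, 80, strand, arm5=(5, 26), arm3=(50, 71))
        smap = decompose(pre)
        expected = oracle_base_labels(80, arm5=(5, 26), arm3=(50, 71))
        for pos in range(pre.interval.start, pre.interval.end + 1):
            lab = smap.locate(pos)
            t = pre.to_transcribed(pos)
            assert (lab.value, lab.mix) == expected[t - 1]


geometry = st.tuples(
    st.integers(0, 15),  # 5' flank
    st.integers(8, 25),  # arm5 length
    st.integers(0, 20),  # loop
    st.integers(8, 25),  # arm3 length
    st.integers(0, 15),  # 3' flank
    st.sampled_from(["both", "5p", "3p", "none"]),
    st.sampled_from(["+", "-"]),
    st.integers(1, 10_000),  # genomic start
)


@settings(max_examples=120, derandomize=True)
@given(geometry)
def test_partition_and_strand_symmetry_fuzzed(geo):
    """Segments tile every fuzzed precursor; labels are strand-symmetric."""
    f5, a5, lp, a3, f3, arms, strand, start = geo
    L = f5 + a5 + lp + a3 + f3
    arm5 = (f5 + 1, f5 + a5) if arms in ("both", "5p") else None
    arm3 = (f5 + a5 + lp + 1, f5 + a5 + lp + a3) if arms in ("both", "3p") else None
    pre = build_pre(start, L, strand, arm5=arm5, arm3=arm3)
    smap = decompose(pre)
    smap.validate_partition()
    expected = oracle_base_labels(L, arm5=arm5, arm3=arm3)
    got = transcribed_labels(pre)
    assert got == expected
    # locate agrees with the per-base expansion
    for pos, lab in smap.iter_base_labels():
        assert smap.locate(pos) == lab
    mirror = build_pre(start, L, "-" if strand == "+" else "+", arm5=arm5, arm3=arm3)
    assert transcribed_labels(mirror) == got


class TestGFF:
    def _write(self, tmp_path, lines):
        p = tmp_path / "mir.gff3"
        p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return p

    def test_two_record_file(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI01;Name=toy-mir-1",
            "1\t.\tmiRNA\t105\t126\t.\t+\t.\tID=MIMAT01;Name=toy-miR-1;Derives_from=MI01",
        ])
        pres = parse_mirna_gff(path)
        assert len(pres) == 1
        pre = pres[0]
        assert pre.id == "toy-mir-1"
        assert pre.interval.start == 100 and pre.interval.end == 180
        assert len(pre.mature_arms) == 1 and pre.mature_arms[0].arm == "5p"

    def test_minus_strand_high_coordinate_mature_is_5p(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA_primary_transcript\t100\t180\t.\t-\t.\tID=MI01;Name=toy-mir-1",
            "1\t.\tmiRNA\t155\t176\t.\t-\t.\tID=MIMAT01;Name=toy-miR-1;Derives_from=MI01",
        ])
        (pre,) = parse_mirna_gff(path)
        assert pre.mature_arms[0].arm == "5p"

    def test_arm_from_name_suffix_wins(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI01;Name=toy-mir-1",
            "1\t.\tmiRNA\t150\t171\t.\t+\t.\tID=M1;Name=toy-miR-1-3p;Derives_from=MI01",
        ])
        (pre,) = parse_mirna_gff(path)
        assert pre.mature_arms[0].arm == "3p"

    def test_mature_outside_precursor_names_both_ids(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI01;Name=toy-mir-1",
            "1\t.\tmiRNA\t170\t195\t.\t+\t.\tID=M1;Name=toy-miR-1;Derives_from=MI01",
        ])
        with pytest.raises(StructureValidationError) as exc:
            parse_mirna_gff(path)
        assert "toy-miR-1" in str(exc.value) and "toy-mir-1" in str(exc.value)

    def test_orphan_mature_raises(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA\t105\t126\t.\t+\t.\tID=M1;Name=toy-miR-1",
        ])
        with pytest.raises(StructureValidationError, match="Derives_from"):
            parse_mirna_gff(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = self._write(tmp_path, [
            "1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI01",
            "1\tmiRNA\t105",
        ])
        with pytest.raises(GFFParseError, match=":3:"):
            parse_mirna_gff(path)

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        pre = build_pre(100, 80, "+", arm5=(5, 26), arm3=(50, 71))
        out = tmp_path / "segments.bed"
        write_substructure_bed([decompose(pre)], out)
        first = out.read_text().splitlines()[0].split("\t")
        assert first[1] == "99" and first[2] == "103"  # 5' mir: 100..103 inclusive
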