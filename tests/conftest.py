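"""Shared fixtures: a small simulated cohort built once per session."""

from __future__ import annotations

import pytest

from mirvarmap import VariantMap, simulate


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 4-population x 30-sample x 40-precursor synthetic cohort."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = simulate.small_config(seed=11, n_precursors=40)
    cfg.n_planted = 5
    return simulate.simulate_cohort(cfg, outdir)


@pytest.fixture(scope="session")
def small_map(small_cohort) -> VariantMap:
    return VariantMap.build(
        small_cohort.vcf_path,
        small_cohort.gff_path,
        small_cohort.panel_path,
        id_table_path=small_cohort.id_table_path,
    )


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path
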