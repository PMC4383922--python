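import dataclasses

import pytest

from mirfunc import funcmir, mirbase_io
from mirfunc.synthetic_fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """One default-condition fixture set shared across the session."""
    outdir = tmp_path_factory.mktemp("fixture_default")
    return generate(FixtureSpec(rng_seed=11), outdir)


def small_spec(seed: int, **overrides) -> FixtureSpec:
    """Compact fixture spec for repeated property-test generation."""
    base = dict(
        rng_seed=seed,
        n_families=8,
        n_experiments=10,
        utr_count=4,
        utr_len_range=(150, 600),
    )
    base.update(overrides)
    return FixtureSpec(**base)


def run_pipeline(fixture_set):
    """Load a fixture set through the readers and run the annotation pipeline."""
    matures = mirbase_io.read_mature_fasta(fixture_set.mature_fasta)
    precursors = mirbase_io.read_hairpin_fasta(fixture_set.hairpin_fasta)
    table = mirbase_io.read_expression_table(fixture_set.counts_tsv)
    pubmed = mirbase_io.read_pubmed_map(fixture_set.pubmed_tsv)
    highconf = mirbase_io.read_highconf_list(fixture_set.highconf_txt)
    calls = funcmir.annotate(precursors, matures, pubmed, table, highconf)
    rows = funcmir.calls_to_rows(calls, precursors, matures)
    return precursors, matures, calls, rows


def rows_match_truth(rows, truth) -> int:
    """Number of annotation rows disagreeing with oracle ground truth."""
    mismatches = 0
    for row in rows:
        t = truth.scores[row["name"]]
        ok = (
            row["pubmed_score"] == t["pubmed"]
            and row["conservation_score"] == t["conservation"]
            and row["expression_score"] == t["expression"]
            and row["mirbase_score"] == t["mirbase"]
            and row["composite"] == t["composite"]
            and row["is_functional"] == t["functional"]
            and row["dominant_mature"] == t["dominant_mature"]
            and (row["secondary_mature"] or "") == t["secondary_mature"]
            and row["n_supporting_criteria"] == t["n_supporting"]
            and row["required_criteria"] == t["required"]
        )
        mismatches += not ok
    return mismatches


def spec_variants(n: int):
    """Deterministic family of varied fixture specs for equivalence sweeps."""
    variants = []
    for i in range(n):
        variants.append(
            small_spec(
                seed=100 + i,
                ortholog_fraction=(0.0, 0.2, 0.5, 1.0)[i % 4],
                two_arm_fraction=(0.0, 0.5, 1.0)[i % 3],
                pubmed_zero_fraction=(0.2, 0.55, 0.9)[i % 3],
                highconf_fraction=(0.0, 0.15, 0.6)[i % 3],
                mean_rpm_range=((0.01, 5.0), (0.5, 30.0), (5.0, 100.0))[i % 3],
                species=(("hsa", "mmu"), mirbase_io.SPECIES_CODES)[i % 2],
            )
        )
    return variants


@pytest.fixture
def make_spec():
    return small_spec


def spec_replace(spec, **kw):
    return dataclasses.replace(spec, **kw)
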