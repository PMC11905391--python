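"""Generator contracts: determinism, planted-structure validity, count model."""

import numpy as np
import pytest

from srnakit.io_formats import extract_window, reverse_complement
from srnakit.synthetic_data import (
    GenerationError,
    SimConfig,
    build_contaminants,
    build_genome,
    default_knockout_effects,
    simulate_libraries,
    simulate_locus_counts,
)

SMALL = SimConfig(seed=7, n_hairpin_loci=6, read_count_per_library=1500,
                  genome_length=60_000, n_genes=5)


class TestBuildGenome:
    def test_deterministic(self):
        a = build_genome(SMALL)
        b = build_genome(SMALL)
        assert a[0][0].seq == b[0][0].seq
        assert [f for f in a[1]] == [f for f in b[1]]
        assert [t.mature_seq for t in a[2]] == [t.mature_seq for t in b[2]]

    def test_mature_and_star_inside_precursor(self):
        genome, _, truth = build_genome(SMALL)
        for t in truth:
            prec = extract_window(genome, t.precursor)
            assert t.mature_seq in prec
            assert t.star_seq in prec

    def test_zero_mismatch_locus_is_perfectly_complementary(self):
        """A mismatch-free stem makes the star the offset reverse complement
        of the mature — the siRNA-like (class-III-style) construction."""
        _, _, truth = build_genome(SMALL)
        perfect = [t for t in truth if t.n_mismatches == 0]
        assert perfect
        for t in perfect:
            rc = reverse_complement(t.mature_seq)
            assert t.star_seq[:-2] == rc[2:]

    def test_location_classes_match_annotation(self):
        genome, features, truth = build_genome(SMALL)
        from srnakit.tag_annotation import classify_location
        for t in truth:
            assert classify_location(t.precursor, features) == t.location_class

    def test_capacity_error(self):
        config = SimConfig(seed=1, genome_length=8000, n_genes=1,
                           n_hairpin_loci=60)
        with pytest.raises(GenerationError):
            build_genome(config)

    def test_expected_tpm_scales_with_knockout_effect(self):
        _, _, truth = build_genome(SMALL)
        for t in truth:
            assert t.expected_tpm_knockout == pytest.approx(
                t.expected_tpm_control * t.knockout_effect)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(contaminant_fraction=0.7, degradation_fraction=0.4)
        with pytest.raises(ValueError):
            SimConfig(knockout_effect={"locus01": 0.0})


class TestSimulateLibraries:
    def test_files_deterministic(self, tmp_path):
        genome, features, truth = build_genome(SMALL)
        sheet1 = simulate_libraries(genome, truth, SMALL, tmp_path / "a",
                                    features=features)
        sheet2 = simulate_libraries(genome, truth, SMALL, tmp_path / "b",
                                    features=features)
        for (_, r1), (_, r2) in zip(sheet1.iterrows(), sheet2.iterrows()):
            assert open(r1["path"]).read() == open(r2["path"]).read()

    def test_no_contaminants_when_fraction_zero(self, tmp_path):
        config = SimConfig(seed=7, n_hairpin_loci=4,
                           read_count_per_library=800,
                           genome_length=60_000, n_genes=5,
                           contaminant_fraction=0.0)
        genome, features, truth = build_genome(config)
        sheet = simulate_libraries(genome, truth, config, tmp_path,
                                   features=features)
        for path in sheet["path"]:
            assert "src=contaminant" not in open(path).read()

    def test_every_defect_class_planted(self, tmp_path):
        genome, features, truth = build_genome(SMALL)
        sheet = simulate_libraries(genome, truth, SMALL, tmp_path,
                                   features=features)
        text = open(sheet["path"][0]).read()
        for cls in ("low_quality", "contains_N", "no_3p_adapter",
                    "has_5p_adapter", "short", "polyA"):
            assert f"defect={cls}" in text


class TestCountModel:
    def test_null_makes_groups_exchangeable_in_mean(self):
        counts = simulate_locus_counts(
            SimConfig(seed=2, n_hairpin_loci=300), null=True)
        control = counts[[f"control_{i}" for i in (1, 2, 3)]].to_numpy()
        knockout = counts[[f"knockout_{i}" for i in (1, 2, 3)]].to_numpy()
        per_locus = np.log2((knockout.mean(axis=1) + 1)
                            / (control.mean(axis=1) + 1))
        assert abs(per_locus.mean()) < 0.1

    def test_knockout_effect_scales_mean_counts(self):
        """A locus at baseline mean ~1000 with effect 0.09 averages ~90 in
        the knockout replicates."""
        config = SimConfig(seed=6, n_hairpin_loci=40,
                           knockout_effect={f"locus{i + 1:02d}": 0.09
                                            for i in range(40)})
        counts = simulate_locus_counts(config)
        ctl = counts[[f"control_{i}" for i in (1, 2, 3)]].to_numpy()
        ko = counts[[f"knockout_{i}" for i in (1, 2, 3)]].to_numpy()
        ratio = ko.sum() / ctl.sum()
        assert ratio == pytest.approx(0.09, rel=0.15)

    def test_default_effect_table_cycles(self):
        effects = default_knockout_effects(12)
        assert len(effects) == 12
        assert all(v > 0 for v in effects.values())


def test_contaminant_reference_kinds():
    records = build_contaminants(SMALL)
    kinds = {r.id.split("_")[0] for r in records}
    assert kinds == {"rRNA", "snoRNA", "snRNA", "tRNA"}
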