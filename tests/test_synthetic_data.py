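"""Determinism, ground-truth structure and recovery properties of the
synthetic-data generator."""

import json

import numpy as np
import pytest

from piratlas.classify import classify_read
from piratlas.core_model import GENOME
from piratlas.synthetic_data import (
    PlantedCluster,
    SampleSpec,
    SyntheticConfig,
    default_config,
    generate_genome,
    generate_library,
    generate_study,
)

EXPECTED_BIOTYPE = {
    "cluster": "piRNA",
    "background": "piRNA",
    "te": "piRNA",
    "mirna": "miRNA",
    "sirna": "siRNA",
    "structural": "structural_excluded",
}


def small_config(seed=0, **overrides):
    cfg = SyntheticConfig(
        seed=seed,
        contigs=[("chrT", 200_000)],
        planted_clusters=[
            PlantedCluster("chrT", 20_000, 6_000, 15.0, "dual", 0.5),
            PlantedCluster("chrT", 60_000, 4_000, 12.0, "uni_plus", 0.0),
        ],
        n_premirna=10, n_endosirna=5, n_structural=8, n_te_insertions=5,
        n_genes=5,
        mirna_reads=500, sirna_reads=200, structural_reads=200,
        te_pirna_reads=200,
        samples=[SampleSpec("g1", "GSC", 2.0, 50_000, True),
                 SampleSpec("s1", "SC", 1.0, 50_000, False)],
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


class TestConfigValidation:
    def test_cluster_outside_contig_rejected(self):
        cfg = small_config()
        cfg.planted_clusters.append(
            PlantedCluster("chrT", 199_000, 5_000, 10.0)
        )
        with pytest.raises(ValueError, match="bounds"):
            cfg.validate()

    def test_duplicate_sample_ids_rejected(self):
        cfg = small_config()
        cfg.samples = [SampleSpec("x", "a"), SampleSpec("x", "b")]
        with pytest.raises(ValueError, match="duplicate"):
            cfg.validate()

    def test_zero_samples_rejected_by_study(self, tmp_path):
        cfg = small_config()
        cfg.samples = []
        with pytest.raises(ValueError):
            generate_study(cfg, tmp_path / "s")

    def test_bad_length_distribution_rejected(self):
        cfg = small_config(length_distribution={25: 0.5, 26: 0.4})
        with pytest.raises(ValueError, match="sums"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_identical_manifests(self, tmp_path):
        fx1 = generate_study(small_config(3), tmp_path / "a")
        fx2 = generate_study(small_config(3), tmp_path / "b")
        assert fx1.manifest["files"] == fx2.manifest["files"]

    def test_different_seed_differs(self, tmp_path):
        fx1 = generate_study(small_config(3), tmp_path / "a")
        fx2 = generate_study(small_config(4), tmp_path / "b")
        assert fx1.manifest["files"] != fx2.manifest["files"]


class TestLibraryStructure:
    @pytest.fixture(scope="class")
    def fixture(self, tmp_path_factory):
        return generate_study(
            small_config(1), tmp_path_factory.mktemp("study") / "s"
        )

    def test_provenance_labels_classify_to_expected_biotype(self, fixture):
        ann = fixture.annotations
        n_ok = n_tot = 0
        for lib in fixture.libraries:
            for read in lib.reads:
                label = fixture.truth.provenance[read.read_id]
                n_tot += 1
                n_ok += (
                    classify_read(read, ann).label == EXPECTED_BIOTYPE[label]
                )
        assert n_ok / n_tot >= 0.99

    def test_read_sequences_match_genome(self, fixture):
        contigs = fixture.genome.as_strings()
        for read in fixture.libraries[0].reads:
            if read.space != GENOME:
                continue
            iv = read.interval
            assert read.sequence == contigs[iv.chrom][iv.start:iv.end]

    def test_spike_totals_as_configured(self, fixture):
        for lib, spec in zip(fixture.libraries, fixture.config.samples):
            assert lib.spike_total() == spec.spike_total

    def test_truth_json_written(self, fixture, tmp_path):
        # manifest lists every output with a checksum
        assert "truth.json" in fixture.manifest["files"]
        assert "genome.fa" in fixture.manifest["files"]


class TestGeneratedStatistics:
    def test_pingpong_fraction_one_gives_partner_for_every_read(self):
        cfg = small_config(
            7,
            planted_clusters=[
                PlantedCluster("chrT", 20_000, 6_000, 15.0, "dual", 1.0)
            ],
            background_reads_per_kb=0.0,
            mirna_reads=0, sirna_reads=0, structural_reads=0,
            te_pirna_reads=0,
        )
        cfg.samples = [SampleSpec("g1", "GSC", 1.0, 1000, True)]
        genome, ann, truth = generate_genome(cfg)
        lib = generate_library(cfg, genome, ann, truth, cfg.samples[0])
        plus_5p = {r.five_prime() for r in lib.reads
                   if r.interval.strand == "+"}
        minus_5p = {r.five_prime() for r in lib.reads
                    if r.interval.strand == "-"}
        # brute-force check: every plus read has a partner at 5'-overlap 10
        unpartnered = [p for p in plus_5p if p + 9 not in minus_5p]
        assert len(unpartnered) / max(len(plus_5p), 1) <= 0.02
        assert truth.pingpong_pairs["g1"]

    def test_zero_background_confines_pirna_reads_to_cluster(self):
        cfg = small_config(
            8,
            planted_clusters=[
                PlantedCluster("chrT", 20_000, 6_000, 15.0, "dual", 0.0)
            ],
            background_reads_per_kb=0.0,
        )
        genome, ann, truth = generate_genome(cfg)
        lib = generate_library(cfg, genome, ann, truth, cfg.samples[0])
        for read in lib.reads:
            if truth.provenance[read.read_id] == "cluster":
                assert 20_000 <= read.interval.start
                assert read.interval.end <= 26_000

    def test_global_scale_doubles_read_count_within_poisson_bound(self):
        counts = {}
        lams = {}
        for scale, name in [(1.0, "a"), (2.0, "b")]:
            cfg = small_config(9)
            cfg.samples = [SampleSpec(name, "c", scale, 1000, False)]
            lams[name] = sum(
                cl.reads_per_kb * cl.length / 1000.0 * scale
                for cl in cfg.planted_clusters
            )
            genome, ann, truth = generate_genome(cfg)
            lib = generate_library(cfg, genome, ann, truth, cfg.samples[0])
            counts[name] = sum(
                1 for r in lib.reads
                if truth.provenance[r.read_id] == "cluster"
            )
        assert lams["b"] == 2 * lams["a"]
        for name in counts:
            assert abs(counts[name] - lams[name]) < 3 * np.sqrt(lams[name])

    def test_length_histogram_matches_distribution(self):
        cfg = small_config(
            10,
            contigs=[("chrT", 200_000)],
            planted_clusters=[
                PlantedCluster("chrT", 10_000, 150_000, 70.0, "dual", 0.0)
            ],
            background_reads_per_kb=0.0,
            n_premirna=0, n_endosirna=0, n_structural=0, n_te_insertions=0,
            n_genes=0,
            mirna_reads=0, sirna_reads=0, structural_reads=0,
            te_pirna_reads=0,
        )
        cfg.samples = [SampleSpec("g1", "c", 1.0, 1000, False)]
        genome, ann, truth = generate_genome(cfg)
        lib = generate_library(cfg, genome, ann, truth, cfg.samples[0])
        lengths = [r.length() for r in lib.reads
                   if truth.provenance[r.read_id] == "cluster"]
        assert len(lengths) >= 10_000
        observed = {
            l: lengths.count(l) / len(lengths) for l in set(lengths)
        }
        tv = 0.5 * sum(
            abs(observed.get(l, 0.0) - p)
            for l, p in cfg.length_distribution.items()
        )
        assert tv < 0.05

    def test_u1_bias_recovered_from_genome(self):
        cfg = small_config(
            11,
            contigs=[("chrT", 2_000_000)],
            planted_clusters=[
                PlantedCluster("chrT", 10_000, 1_900_000, 6.0, "uni_plus", 0.0)
            ],
            background_reads_per_kb=0.0,
            n_premirna=0, n_endosirna=0, n_structural=0, n_te_insertions=0,
            n_genes=0,
            mirna_reads=0, sirna_reads=0, structural_reads=0,
            te_pirna_reads=0,
        )
        cfg.samples = [SampleSpec("g1", "c", 1.0, 1000, False)]
        genome, ann, truth = generate_genome(cfg)
        lib = generate_library(cfg, genome, ann, truth, cfg.samples[0])
        firsts = [r.sequence[0] for r in lib.reads]
        frac_u = firsts.count("T") / len(firsts)
        assert frac_u == pytest.approx(cfg.u1_prob, abs=0.02)


def test_default_config_is_valid_and_has_condition_contrast():
    cfg = default_config(0)
    cfg.validate()
    conditions = {s.condition for s in cfg.samples}
    assert conditions == {"GSC", "SC"}
    gsc = [s for s in cfg.samples if s.condition == "GSC"]
    sc = [s for s in cfg.samples if s.condition == "SC"]
    assert all(s.pingpong for s in gsc) and not any(s.pingpong for s in sc)
    assert gsc[0].global_scale == 3.0 and sc[0].global_scale == 1.0
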