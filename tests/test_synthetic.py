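import numpy as np
import pytest

from gramclass.ngram_features import build_feature_matrix, count_ngrams, enumerate_grams
from gramclass.synthetic import (
    SyntheticSpec,
    fourteen_class_spec,
    generate_dataset,
    make_motif_sets,
)


class TestMotifSets:
    def test_disjoint_across_classes(self):
        truth = make_motif_sets(SyntheticSpec(n_classes=2, motifs_per_class=1, motif_length=3))
        motifs = truth.all_motifs
        assert len(motifs) == len(set(motifs)) == 2

    def test_fourteen_class_capacity(self):
        truth = make_motif_sets(fourteen_class_spec())
        motifs = truth.all_motifs
        assert len(motifs) == len(set(motifs)) == 70
        assert all(len(m) == 4 for m in motifs)

    def test_capacity_exceeded_rejected(self):
        spec = SyntheticSpec(n_classes=20, motifs_per_class=4, motif_length=2)
        with pytest.raises(ValueError, match="distinct"):
            make_motif_sets(spec)

    def test_seeded_determinism(self):
        a = make_motif_sets(SyntheticSpec(seed=5))
        b = make_motif_sets(SyntheticSpec(seed=5))
        assert a.class_motifs == b.class_motifs


class TestGenerateDataset:
    def test_record_accounting(self, strong14_dataset):
        sset, _ = strong14_dataset
        assert len(sset) == 700
        counts = {c: 0 for c in sset.class_names}
        for rec in sset.records:
            counts[rec.label] += 1
            assert len(rec.sequence) == 500
        assert set(counts.values()) == {50}

    def test_byte_identical_for_same_seed(self):
        spec = SyntheticSpec(n_classes=3, n_per_class=5, length=200, seed=13)
        a, _ = generate_dataset(spec)
        b, _ = generate_dataset(SyntheticSpec(n_classes=3, n_per_class=5, length=200, seed=13))
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_null_spec_is_pure_background(self):
        spec = SyntheticSpec(n_classes=2, n_per_class=4, planting_rate=0.0, noise_rate=0.0, seed=3)
        sset, _ = generate_dataset(spec)
        assert all(set(r.sequence) <= set("ACGT") for r in sset.records)

    def test_planted_kmers_enriched_in_own_class(self):
        spec = SyntheticSpec(
            n_classes=3, n_per_class=20, length=500, planting_rate=20.0, noise_rate=0.0, seed=2
        )
        sset, truth = generate_dataset(spec)
        grams = enumerate_grams(spec.motif_length)
        by_class: dict[str, np.ndarray] = {}
        for label in sset.class_names:
            counts = [
                count_ngrams(r.sequence, spec.motif_length)
                for r in sset.records
                if r.label == label
            ]
            by_class[label] = np.mean(counts, axis=0)
        # Enrichment is checked in aggregate: windows straddling insertion
        # boundaries can elevate a motif in a foreign class, so single
        # motifs occasionally fail a strict per-motif comparison.
        n_enriched, margins = 0, []
        for label, motifs in truth.class_motifs.items():
            for m in motifs:
                j = grams.index(m)
                own = by_class[label][j]
                others = [by_class[o][j] for o in sset.class_names if o != label]
                margins.append(own - max(others))
                n_enriched += own > max(others)
        assert n_enriched >= 0.8 * len(margins)
        assert np.mean(margins) > 0

    def test_gc_content_respected(self):
        spec = SyntheticSpec(
            n_classes=2, n_per_class=10, length=2000,
            planting_rate=0.0, noise_rate=0.0, gc_content=0.7, seed=1,
        )
        sset, _ = generate_dataset(spec)
        gc = np.mean([
            (r.sequence.count("G") + r.sequence.count("C")) / len(r.sequence)
            for r in sset.records
        ])
        assert abs(gc - 0.7) < 0.02

    def test_signal_monotone_in_planting_rate(self):
        """Mean within-class frequency of planted k-mers is non-decreasing
        in the planting rate, averaged over seeds."""
        mean_freq = []
        for rho in (0.0, 5.0, 15.0):
            freqs = []
            for seed in range(5):
                spec = SyntheticSpec(
                    n_classes=2, n_per_class=8, length=400, planting_rate=rho, seed=seed
                )
                sset, truth = generate_dataset(spec)
                grams = enumerate_grams(spec.motif_length)
                for label, motifs in truth.class_motifs.items():
                    rows = [r for r in sset.records if r.label == label]
                    counts = np.mean(
                        [count_ngrams(r.sequence, spec.motif_length) for r in rows], axis=0
                    )
                    freqs.extend(counts[grams.index(m)] for m in motifs)
            mean_freq.append(np.mean(freqs))
        assert mean_freq[0] <= mean_freq[1] <= mean_freq[2]

    def test_impossible_placement_raises(self):
        # room for at most 5 non-overlapping 3-mers, Poisson(4.9) often asks more
        spec = SyntheticSpec(
            n_classes=2, n_per_class=10, length=15,
            motifs_per_class=2, motif_length=3, planting_rate=4.9, seed=0,
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            generate_dataset(spec)

    def test_validation_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_classes=1).validate()
        with pytest.raises(ValueError):
            SyntheticSpec(noise_rate=1.0).validate()
        with pytest.raises(ValueError):
            SyntheticSpec(length=40, planting_rate=15.0).validate()

    def test_null_planted_columns_rank_uniform(self):
        """With no planting, 'planted' columns score like any other column."""
        from scipy import stats

        from gramclass.selection import feature_scores

        spec = SyntheticSpec(planting_rate=0.0, seed=6)
        sset, truth = generate_dataset(spec)
        fm = build_feature_matrix(sset)
        scores = feature_scores(fm.X, fm.y, fm.n_classes)
        ranks = np.argsort(np.argsort(-scores))
        idx = [fm.feature_names.index(m) for m in truth.all_motifs]
        u = (ranks[idx] + 0.5) / fm.n_features
        assert stats.kstest(u, "uniform").pvalue > 0.01
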