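"""Deisotoping: co-localization, envelope assembly, conservation."""

import numpy as np
import pytest

from maldimatch.deisotope import (
    ClusterPeakSet,
    DeisotopeParams,
    build_cluster_peaks,
    colocalization,
    deisotope_all,
    deisotope_cluster,
    deisotope_exhaustive,
)
from maldimatch.isotopes import ISOTOPE_SPACING, PROTON_MASS, envelope_ratios


def make_envelope_peaks(mono: float, intensity: float, image: np.ndarray, n_iso=4):
    ratios = envelope_ratios(mono, n_iso)
    mz = mono + np.arange(n_iso) * ISOTOPE_SPACING
    inten = intensity * ratios
    images = np.outer(inten / inten[0], image * intensity / image.mean())
    return mz, inten, images


def peak_set(*envelopes, cluster_id=0):
    mz = np.concatenate([e[0] for e in envelopes])
    inten = np.concatenate([e[1] for e in envelopes])
    images = np.vstack([e[2] for e in envelopes])
    order = np.argsort(mz)
    return ClusterPeakSet(cluster_id, mz[order], inten[order], images[order])


class TestColocalization:
    def test_identity_is_one(self, rng):
        img = rng.random(50)
        assert colocalization(img, img) == pytest.approx(1.0)

    def test_negation_about_mean_is_minus_one(self, rng):
        img = rng.random(50)
        assert colocalization(img, 2 * img.mean() - img) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            colocalization(np.ones(10), np.arange(10.0))

    def test_disjoint_regions_anticorrelate(self, small_sim):
        """Ion images of peptides planted in different regions correlate < 0."""
        from maldimatch.ims import ion_image, tic_normalize

        cfg, _, truth, ds = small_sim
        ds = tic_normalize(ds)
        r0 = truth.imaged().query("ims_region == 0").iloc[0]
        r1 = truth.imaged().query("ims_region == 1").iloc[0]
        a = ion_image(ds, r0["mass"] + PROTON_MASS, 0.15).values
        b = ion_image(ds, r1["mass"] + PROTON_MASS, 0.15).values
        assert colocalization(a, b) < 0


class TestDeisotopeCluster:
    def test_clean_envelope_collapses_to_one_entry(self, rng):
        image = 1.0 + rng.random(30)
        peaks = peak_set(make_envelope_peaks(1200.0, 100.0, image))
        out = deisotope_cluster(peaks)
        assert len(out.entries) == 1
        e = out.entries[0]
        assert e.mono_mz == pytest.approx(1200.0)
        assert len(e.members) == 4

    def test_overlapping_envelopes_split_by_colocalization(self, rng):
        """Two peaks 1.00 Da apart but in disjoint regions stay separate."""
        img_a = np.concatenate([1.0 + rng.random(15), np.zeros(15)])
        img_b = np.concatenate([np.zeros(15), 1.0 + rng.random(15)])
        mz = np.array([1000.0, 1001.0])
        inten = np.array([100.0, 60.0])  # ratio plausible for an isotope pair
        peaks = ClusterPeakSet(0, mz, inten, np.vstack([img_a * 100, img_b * 60]))
        out = deisotope_cluster(peaks)
        assert len(out.entries) == 2

    def test_spacing_outside_tolerance_stays_separate(self, rng):
        image = 1.0 + rng.random(20)
        mz = np.array([1000.0, 1001.25])  # 1.25 Da: outside 1.00235 +/- 0.15
        inten = np.array([100.0, 53.0])
        peaks = ClusterPeakSet(0, mz, inten, np.vstack([image * 100, image * 53]))
        out = deisotope_cluster(peaks)
        assert len(out.entries) == 2

    def test_intensity_far_from_averagine_expectation_rejected(self, rng):
        image = 1.0 + rng.random(20)
        mz = np.array([1000.0, 1000.0 + ISOTOPE_SPACING])
        # expected ratio at 1 kDa is ~0.54; 2.0 is far outside +/-50%
        inten = np.array([100.0, 200.0])
        peaks = ClusterPeakSet(0, mz, inten, np.vstack([image * 100, image * 200]))
        out = deisotope_cluster(peaks)
        assert len(out.entries) == 2

    def test_empty_peak_set_yields_empty_list(self):
        peaks = ClusterPeakSet(0, np.zeros(0), np.zeros(0), np.zeros((0, 10)))
        out = deisotope_cluster(peaks)
        assert out.entries == [] and out.unassigned == []

    def test_peak_conservation(self, rng):
        image = 1.0 + rng.random(25)
        peaks = peak_set(
            make_envelope_peaks(800.0, 50.0, image),
            make_envelope_peaks(1500.3, 80.0, 1.0 + rng.random(25)),
            make_envelope_peaks(2400.7, 20.0, 1.0 + rng.random(25)),
        )
        out = deisotope_cluster(peaks)
        assert out.n_peaks() == len(peaks)

    def test_greedy_matches_exhaustive_on_small_instances(self, rng):
        """On small peak sets the greedy assembly explains as many peaks as
        the exhaustive partition search, and yields the same envelopes."""
        for trial in range(10):
            n_env = int(rng.integers(1, 4))
            envs = []
            used = []
            for _ in range(n_env):
                while True:
                    mono = float(rng.uniform(700, 2500))
                    if all(abs(mono - u) > 8 for u in used):
                        break
                used.append(mono)
                envs.append(
                    make_envelope_peaks(mono, float(rng.uniform(20, 200)), 1.0 + rng.random(20))
                )
            peaks = peak_set(*envs)
            greedy = deisotope_cluster(peaks)
            exact = deisotope_exhaustive(peaks)
            assert sorted(e.mono_mz for e in greedy.entries) == pytest.approx(
                sorted(e.mono_mz for e in exact.entries)
            )
            assert sorted(len(e.members) for e in greedy.entries) == sorted(
                len(e.members) for e in exact.entries
            )


class TestDeisotopeAll:
    def test_recovers_planted_envelopes(self, small_sim):
        from maldimatch.ims import tic_normalize

        cfg, _, truth, ds = small_sim
        labels = truth.region_map[ds.coordinates[:, 1], ds.coordinates[:, 0]]
        per_cluster, pooled = deisotope_all(tic_normalize(ds), labels)
        imaged = truth.imaged()
        recovered = 0
        for _, row in imaged.iterrows():
            ml = per_cluster[int(row["ims_region"])]
            if len(ml.entries) and np.min(np.abs(ml.mono_mzs - (row["mass"] + PROTON_MASS))) <= 0.05:
                recovered += 1
        assert recovered >= 0.95 * len(imaged)

    def test_single_cluster_equals_whole_image(self, small_sim):
        from maldimatch.ims import tic_normalize

        _, _, _, ds = small_sim
        ds = tic_normalize(ds)
        labels = np.zeros(ds.n_pixels, dtype=int)
        per_cluster, pooled = deisotope_all(ds, labels)
        assert list(per_cluster) == [0]
        assert [e.mono_mz for e in pooled.entries] == sorted(
            e.mono_mz for e in pooled.entries
        )

    def test_empty_dataset_yields_empty_lists(self):
        from maldimatch.ims import IMSDataset

        ds = IMSDataset(
            np.array([[0, 0], [1, 0]]),
            [np.array([700.0]), np.zeros(0)],
            [np.array([1.0]), np.zeros(0)],
            (600.0, 1000.0),
        )
        labels = np.array([0, 1])
        per_cluster, pooled = deisotope_all(ds, labels)
        assert len(per_cluster[1].entries) == 0

    def test_pooled_list_deduplicates_within_tolerance(self, small_sim):
        from maldimatch.ims import tic_normalize

        _, _, truth, ds = small_sim
        labels = truth.region_map[ds.coordinates[:, 1], ds.coordinates[:, 0]]
        _, pooled = deisotope_all(tic_normalize(ds), labels)
        mzs = pooled.mono_mzs
        assert np.all(np.diff(np.sort(mzs)) > 0.1)


def test_build_cluster_peaks_centroids_match_planted(small_sim):
    from maldimatch.ims import tic_normalize

    cfg, _, truth, ds = small_sim
    labels = truth.region_map[ds.coordinates[:, 1], ds.coordinates[:, 0]]
    peaks = build_cluster_peaks(tic_normalize(ds), labels, 0)
    planted = truth.imaged().query("ims_region == 0")
    mono_positions = planted["mass"].to_numpy() + PROTON_MASS
    for m in mono_positions:
        assert np.min(np.abs(peaks.mz - m)) <= 0.05
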