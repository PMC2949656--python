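import numpy as np
import pandas as pd
import pytest

from apocrine.acgh import (
    CloneCall,
    aggregate_clone,
    call_status,
    call_tumor,
    calls_to_frame,
    exclude_sparse_clones,
    genome_plot,
    perturbation_rate,
)
from apocrine.io import AcghExperiment, CentromereMap, DataError
from apocrine.synthetic import generate_acgh


def _spots(entries):
    return pd.DataFrame(entries, columns=["cy3", "cy5", "snr", "valid"])


class TestAggregateClone:
    def test_concordant_quadruplicate(self):
        spots = _spots([(1.5, 1.0, 20.0, True)] * 4)
        assert aggregate_clone(spots) == pytest.approx(1.5)

    def test_replicate_sd_filter(self):
        # log2 ratios with SD 0.3 > 0.1 -> missing
        ratios = 2.0 ** np.array([-0.3, 0.0, 0.3, 0.45])
        spots = _spots([(r, 1.0, 20.0, True) for r in ratios])
        assert np.isnan(aggregate_clone(spots))

    def test_low_snr_spot_excluded_before_median(self):
        # SD cap relaxed so only the snr rule acts: median of [1.0, 1.0, 1.2]
        spots = _spots(
            [
                (1.0, 1.0, 20.0, True),
                (1.0, 1.0, 20.0, True),
                (2.0, 1.0, 1.0, True),  # snr below 3: dropped
                (1.2, 1.0, 20.0, True),
            ]
        )
        assert aggregate_clone(spots, sd_max=1.0) == pytest.approx(1.0)
        # at the default replicate-SD cap the surviving spots are too
        # dispersed (log2 SD 0.15 > 0.1) and the clone is missing
        assert np.isnan(aggregate_clone(spots))

    def test_all_spots_invalid_gives_missing(self):
        spots = _spots([(1.0, 1.0, 20.0, False)] * 4)
        assert np.isnan(aggregate_clone(spots))

    def test_nonpositive_intensity_invalidated(self):
        spots = _spots([(0.0, 1.0, 20.0, True), (1.5, 1.0, 20.0, True)])
        with pytest.warns(UserWarning, match="non-positive"):
            assert aggregate_clone(spots) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            aggregate_clone(_spots([]))


class TestCallStatus:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (1.0, "normal"),
            (1.5, "gain"),
            (0.5, "loss"),
            (2.5, "amplicon"),
            (1.2, "normal"),  # strict inequality at the gain bound
            (0.8, "normal"),
            (2.0, "gain"),
            (float("nan"), "missing"),
        ],
    )
    def test_thresholds(self, ratio, expected):
        assert call_status(ratio) == expected

    def test_literal_log_reading(self):
        # under the verbatim log reading, ratio 2.5 -> log2 = 1.32 < 2: not amplicon
        assert call_status(2.5, literal_log=True) == "gain"
        assert call_status(2.5, literal_log=False) == "amplicon"


class TestSparseClones:
    def _experiment(self, missing_pattern):
        """missing_pattern: clone -> list of per-tumor booleans (True=missing)."""
        clones = pd.DataFrame(
            {"chromosome": ["1"] * len(missing_pattern), "position": [1e6] * len(missing_pattern)},
            index=pd.Index(list(missing_pattern), name="clone_id"),
        )
        rows = []
        for clone, pattern in missing_pattern.items():
            for t, is_missing in enumerate(pattern):
                rows.append(
                    (clone, f"T{t}", 1.0, 1.0, 0.5 if is_missing else 20.0, True)
                )
        spots = pd.DataFrame(
            rows, columns=["clone_id", "tumor_id", "cy3", "cy5", "snr", "valid"]
        )
        return AcghExperiment(clones=clones, spots=spots)

    def test_majority_missing_removed(self):
        exp = self._experiment({"c1": [True, True, True, False, False]})
        assert exclude_sparse_clones(exp) == []

    def test_never_missing_kept(self):
        exp = self._experiment({"c1": [False] * 5})
        assert exclude_sparse_clones(exp) == ["c1"]

    def test_exactly_half_missing_kept(self):
        exp = self._experiment({"c1": [True, True, False, False]})
        assert exclude_sparse_clones(exp) == ["c1"]


class TestPerturbationRate:
    def _cmap(self):
        return CentromereMap(
            pd.DataFrame(
                {"centromere": [100.0, 50.0], "length": [250.0, 120.0]},
                index=pd.Index(["1", "2"], name="chromosome"),
            )
        )

    def _call(self, clone, chrom, pos, status, ratio=1.0):
        return CloneCall(
            clone_id=clone,
            chromosome=chrom,
            position=pos,
            arm="p" if pos < (100.0 if chrom == "1" else 50.0) else "q",
            median_ratio=float("nan") if status == "missing" else ratio,
            status=status,
        )

    def test_all_normal_rate_zero(self):
        calls = [self._call(f"c{i}", "1", 10.0 + i, "normal") for i in range(6)]
        assert perturbation_rate(calls, self._cmap()).rate == 0.0

    def test_all_gained_rate_one(self):
        calls = [self._call(f"c{i}", "1", 10.0 + i, "gain", 1.5) for i in range(6)]
        assert perturbation_rate(calls, self._cmap()).rate == 1.0

    def test_two_arm_hand_example(self):
        # arm 1p: 2 altered of 4; arm 2q: 0 of 4 -> rate mean(0.5, 0) = 0.25
        calls = (
            [self._call(f"a{i}", "1", 10.0 + i, "gain" if i < 2 else "normal", 1.5 if i < 2 else 1.0) for i in range(4)]
            + [self._call(f"b{i}", "2", 60.0 + i, "normal") for i in range(4)]
        )
        summary = perturbation_rate(calls, self._cmap())
        assert summary.rate == pytest.approx(0.25)
        assert summary.per_arm.loc[("1", "p"), "fraction"] == pytest.approx(0.5)

    def test_missing_clones_not_informative(self):
        calls = [self._call(f"c{i}", "1", 10.0 + i, "missing") for i in range(3)] + [
            self._call("c9", "1", 13.0, "gain", 1.5)
        ]
        assert perturbation_rate(calls, self._cmap()).rate == 1.0

    def test_unknown_chromosome_rejected(self):
        calls = [self._call("c1", "7", 10.0, "normal")]
        with pytest.raises(DataError):
            perturbation_rate(calls, self._cmap())

    def test_amplicon_counts_as_altered(self):
        calls = [
            self._call("c1", "1", 10.0, "amplicon", 3.0),
            self._call("c2", "1", 11.0, "normal"),
        ]
        assert perturbation_rate(calls, self._cmap()).rate == pytest.approx(0.5)


class TestSyntheticRecovery:
    def test_noiseless_profile_recovered_exactly(self):
        sc = generate_acgh(n_clones=300, noise_sd=0.0, low_snr_fraction=0.0, seed=1)
        calls = call_tumor(sc.experiment, "T1", sc.centromeres)
        assert all(c.status == sc.truth.clone_status[c.clone_id] for c in calls)
        rate = perturbation_rate(calls, sc.centromeres).rate
        assert rate == pytest.approx(sc.truth.perturbation_rate, abs=1e-12)

    def test_noisy_rate_within_tolerance(self):
        sc = generate_acgh(n_clones=500, noise_sd=0.05, seed=2)
        calls = call_tumor(sc.experiment, "T1", sc.centromeres)
        rate = perturbation_rate(calls, sc.centromeres).rate
        assert abs(rate - sc.truth.perturbation_rate) <= 0.02

    def test_rate_invariant_to_clone_order(self):
        sc = generate_acgh(n_clones=200, seed=3)
        calls = call_tumor(sc.experiment, "T1", sc.centromeres)
        rate1 = perturbation_rate(calls, sc.centromeres).rate
        rate2 = perturbation_rate(list(reversed(calls)), sc.centromeres).rate
        assert rate1 == rate2


def test_genome_plot_writes_figure(tmp_path):
    sc = generate_acgh(n_clones=100, seed=4)
    calls = call_tumor(sc.experiment, "T1", sc.centromeres)
    out = tmp_path / "profile.png"
    genome_plot(calls, sc.centromeres, out)
    assert out.stat().st_size > 0
    frame = calls_to_frame(calls)
    assert set(frame["status"]) <= {"loss", "normal", "gain", "amplicon", "missing"}
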