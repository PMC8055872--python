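import numpy as np
import pytest

from hippus.preprocess import zscore
from hippus.sampen import SampEnParams, epoch_average_sampen, sample_entropy
from oracles import sampen_bruteforce


class TestSampleEntropy:
    def test_constant_segment_zero_entropy(self):
        res = sample_entropy(np.zeros(50))
        assert res.h == 0.0
        assert res.counts_m == res.counts_m1 > 0

    def test_periodic_pattern_zero_entropy(self):
        x, _ = zscore(np.tile([1.0, 2.0, 3.0], 20))
        res = sample_entropy(x, SampEnParams(m=2, r=0.2))
        assert res.h == 0.0  # every length-2 match extends to length 3

    def test_matches_bruteforce_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(50, 300))
            x, _ = zscore(rng.normal(size=n))
            for m, r in ((2, 0.2), (1, 0.5), (3, 0.3)):
                res = sample_entropy(x, SampEnParams(m=m, r=r))
                h, b, a = sampen_bruteforce(x, m, r)
                assert res.counts_m == b and res.counts_m1 == a
                if np.isnan(h):
                    assert not res.defined
                else:
                    assert res.h == pytest.approx(h, abs=0, rel=1e-14)

    def test_affine_invariance_through_zscore(self, rng):
        x = rng.normal(size=200)
        z1, _ = zscore(x)
        z2, _ = zscore(5.0 * x - 3.0)
        assert sample_entropy(z1).h == pytest.approx(sample_entropy(z2).h, rel=1e-12)

    def test_noise_more_complex_than_sinusoid(self):
        t = np.arange(400)
        hs_noise, hs_sine = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            zn, _ = zscore(rng.normal(size=400))
            zs, _ = zscore(np.sin(2 * np.pi * t / 40 + rng.uniform(0, 6.28)))
            hs_noise.append(sample_entropy(zn).h)
            hs_sine.append(sample_entropy(zs).h)
        assert np.mean(hs_noise) > np.mean(hs_sine)

    def test_nonnegative_when_defined(self, rng):
        for _ in range(20):
            z, _ = zscore(rng.normal(size=120))
            res = sample_entropy(z)
            if res.defined:
                assert res.h >= 0

    def test_undefined_marker(self):
        # steps of 1 >> r: no template pair ever matches
        res = sample_entropy(np.arange(20.0), SampEnParams(m=2, r=0.2))
        assert not res.defined and np.isnan(res.h)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, np.nan, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            SampEnParams(m=0)
        with pytest.raises(ValueError):
            SampEnParams(r=0.0)


class TestEpochAveraging:
    def _epochset(self, per_epoch_values, monkeypatch):
        """EpochSet stub whose epochs yield prescribed SampEn values."""
        import hippus.sampen as mod

        left_vals, right_vals = per_epoch_values
        n = max(len(left_vals), len(right_vals))

        class ES:
            subject_id = "stub"
            n_epochs = n
            kept = np.ones(n, bool)
            zscored_left = np.zeros((n, 1))
            zscored_right = np.zeros((n, 1))

        seq = {}
        for k, v in enumerate(left_vals):
            seq[(k, "L")] = v
        for k, v in enumerate(right_vals):
            seq[(k, "R")] = v

        calls = {"i": 0}

        def fake(x, params):
            idx = calls["i"]
            calls["i"] += 1
            eye = "L" if idx < n else "R"
            v = seq.get((idx % n, eye), np.nan)
            return mod.SampEnResult(h=v, counts_m=1, counts_m1=1, n_templates=1)

        monkeypatch.setattr(mod, "sample_entropy", fake)
        return ES()

    def test_eye_then_epoch_average(self, monkeypatch):
        es = self._epochset(([0.1, 0.2], [0.3, 0.3]), monkeypatch)
        assert epoch_average_sampen(es) == pytest.approx((0.15 + 0.3) / 2)

    def test_undefined_epoch_excluded(self, monkeypatch):
        es = self._epochset(([0.1, np.nan, 0.3], [0.2, 0.2, 0.2]), monkeypatch)
        assert epoch_average_sampen(es) == pytest.approx((0.2 + 0.2) / 2)

    def test_identical_eyes_equals_single_eye_mean(self, rng):
        from hippus.preprocess import EpochSet

        z = np.vstack([zscore(rng.normal(size=200))[0] for _ in range(3)])
        es = EpochSet(
            subject_id="s", fs=300.0, epoch_len_s=5.0,
            epochs_left=z, epochs_right=z.copy(),
            zscored_left=z, zscored_right=z.copy(),
            missing_frac_left=np.zeros(3), missing_frac_right=np.zeros(3),
            kept=np.ones(3, bool),
        )
        single_eye = np.mean([sample_entropy(z[k]).h for k in range(3)])
        assert epoch_average_sampen(es) == pytest.approx(single_eye)
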