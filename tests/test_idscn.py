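"""Template network perturbation: IDSCN deltas, Z scores, altered edges, severity."""

import numpy as np
import pandas as pd
import pytest

from oracles import correlation_matrix
from scnkit.idscn import (
    IDSCN,
    altered_edge_profile,
    call_altered_edges,
    idscn_z,
    null_calibration,
    perturbed_scn,
    severity_association,
)
from scnkit.simulate import uniform_correlation


def _controls(n, p, seed=0, r=0.3):
    rng = np.random.default_rng(seed)
    cov = uniform_correlation(p, r)
    w, v = np.linalg.eigh(cov)
    X = rng.standard_normal((n, p)) @ (v * np.sqrt(np.clip(w, 0, None))).T
    return pd.DataFrame(X, columns=[f"R{i}" for i in range(p)])


class TestPerturbedSCN:
    def test_matches_brute_force_over_six_rows(self):
        ctrl = _controls(5, 3, seed=1)
        subject = pd.Series({"R0": 0.5, "R1": -1.2, "R2": 0.3})
        net = perturbed_scn(ctrl, subject, ["R0", "R1", "R2"])
        stacked = np.vstack([ctrl.to_numpy(), subject.to_numpy()])
        expected = correlation_matrix(stacked)
        np.fill_diagonal(expected, 0.0)
        assert np.abs(net.weights - expected).max() < 1e-12

    def test_control_like_subject_barely_moves_edges_at_large_n(self):
        ctrl = _controls(500, 4, seed=2)
        net0 = perturbed_scn(ctrl.iloc[:-1], ctrl.iloc[-1], [f"R{i}" for i in range(4)])
        base = np.corrcoef(ctrl.iloc[:-1].to_numpy(), rowvar=False)
        np.fill_diagonal(base, 0.0)
        assert np.abs(net0.weights - base).max() < 0.01

    def test_missing_region_and_empty_controls_rejected(self):
        ctrl = _controls(10, 3)
        with pytest.raises(ValueError, match="missing region"):
            perturbed_scn(ctrl, pd.Series({"R0": 1.0}), ["R0", "R1", "R2"])
        with pytest.raises(ValueError, match="at least 4"):
            perturbed_scn(ctrl.head(2), ctrl.iloc[-1], ["R0", "R1", "R2"])


class TestIdscnZ:
    def test_zero_delta_gives_zero_z(self):
        r = uniform_correlation(3, 0.4)
        z = idscn_z(np.zeros((3, 3)), r, n=100)
        off = z[~np.eye(3, dtype=bool)]
        assert np.all(off == 0)

    def test_printed_formula_hand_arithmetic(self):
        # delta 0.05, r 0.5, n 401: Z = 0.05 / ((1 - 0.25)/400) = 26.666...
        z = idscn_z(np.array([[0.0, 0.05], [0.05, 0.0]]),
                    np.array([[1.0, 0.5], [0.5, 1.0]]), n=401)
        assert z[0, 1] == pytest.approx(0.05 * 400 / 0.75)
        assert z[0, 1] == pytest.approx(26.666666666666668)

    def test_sqrt_variant_hand_arithmetic(self):
        z = idscn_z(np.array([[0.0, 0.05], [0.05, 0.0]]),
                    np.array([[1.0, 0.5], [0.5, 1.0]]), n=401, variant="sqrt")
        assert z[0, 1] == pytest.approx(0.05 * 20 / 0.75)

    def test_saturated_edge_flagged_non_finite(self):
        z = idscn_z(np.array([[0.0, 0.1], [0.1, 0.0]]),
                    np.array([[1.0, 1.0], [1.0, 1.0]]), n=50)
        assert np.isnan(z[0, 1])

    def test_small_control_group_rejected(self):
        with pytest.raises(ValueError):
            idscn_z(np.zeros((2, 2)), np.eye(2), n=3)


class TestCallAlteredEdges:
    def test_zero_z_calls_nothing(self):
        mask = ~np.eye(4, dtype=bool)
        altered, p = call_altered_edges(np.zeros((4, 4)), mask, list("abcd"))
        assert altered == []
        assert np.allclose(p[np.triu(mask, 1)], 1.0)

    def test_one_enormous_z_among_many_nulls(self):
        p = 50  # 1225 edges
        rng = np.random.default_rng(0)
        z = rng.normal(0, 0.5, size=(p, p))
        z = (z + z.T) / 2
        labels = [f"n{i}" for i in range(p)]
        z[3, 7] = z[7, 3] = 12.0
        mask = ~np.eye(p, dtype=bool)
        altered, _ = call_altered_edges(z, mask, labels)
        assert altered == [("n3", "n7")]


class TestProfiles:
    @staticmethod
    def _run(n_ctrl=40, n_case=6, p=5, seed=3):
        ctrl = _controls(n_ctrl, p, seed=seed)
        cases = _controls(n_case, p, seed=seed + 1)
        cases.insert(0, "subject_id", [f"c{i}" for i in range(n_case)])
        est = IDSCN(nodes=[f"R{i}" for i in range(p)]).fit(ctrl)
        return est.transform(cases)

    def test_counting_identities(self):
        results = self._run()
        profile = altered_edge_profile(results)
        # unipartite handshake: per-node counts sum to 2x totals
        assert profile.per_node.sum() == 2 * profile.totals.sum()
        for r, total in zip(results, profile.totals):
            assert r.n_altered == total

    def test_subject_order_independence(self):
        ctrl = _controls(40, 4, seed=9)
        cases = _controls(5, 4, seed=10)
        cases.insert(0, "subject_id", [f"c{i}" for i in range(5)])
        est = IDSCN(nodes=[f"R{i}" for i in range(4)]).fit(ctrl)
        fwd = est.transform(cases)
        rev = est.transform(cases.iloc[::-1])
        by_id_f = {r.subject_id: r.z for r in fwd}
        by_id_r = {r.subject_id: r.z for r in rev}
        for sid in by_id_f:
            assert np.array_equal(by_id_f[sid], by_id_r[sid])

    def test_delta_equals_stored_network_difference(self):
        ctrl = _controls(30, 4, seed=5)
        case = _controls(1, 4, seed=6).iloc[0]
        nodes = [f"R{i}" for i in range(4)]
        est = IDSCN(nodes=nodes).fit(ctrl)
        res = est.transform_subject(case, "s")
        pert = perturbed_scn(est.control_residuals_, case, nodes)
        recomputed = pert.weights - est.control_net_.weights
        off = ~np.eye(4, dtype=bool)
        assert np.array_equal(res.delta[off], recomputed[off])

    def test_mismatched_networks_rejected(self):
        a = self._run(p=4, seed=1)
        b = self._run(p=5, seed=2)
        with pytest.raises(ValueError, match="share one network"):
            altered_edge_profile([a[0], b[0]])


class TestSeverity:
    def test_perfect_linear_association(self):
        sev = np.linspace(0.1, 0.9, 20)
        out = severity_association(3 * sev, sev)
        assert out["r"] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            severity_association(np.ones(20), np.linspace(0, 1, 20))

    def test_adjusted_regression_same_direction(self):
        rng = np.random.default_rng(7)
        sev = rng.uniform(0, 1, 100)
        age = rng.uniform(20, 60, 100)
        vals = 2.0 * sev + 0.01 * age + rng.normal(0, 0.3, 100)
        adjust = pd.DataFrame({"age": age, "age2": age**2,
                               "sex": rng.integers(0, 2, 100)})
        out = severity_association(vals, sev, adjust=adjust)
        assert out["r"] > 0
        assert out["adjusted_slope"] == pytest.approx(2.0, abs=0.5)
        assert out["adjusted_p"] < 1e-6

    def test_null_calibration_rejection_rate(self):
        # independent values vs severity: ~5% rejections at alpha = .05
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            out = severity_association(rng.normal(size=300), rng.uniform(0, 1, 300))
            hits += out["p"] < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestNullBehavior:
    def test_delta_shrinks_with_control_group_size(self):
        probe = _controls(20, 5, seed=100)
        maxes = []
        for n in (50, 200, 800):
            ctrl = _controls(n, 5, seed=n)
            est = IDSCN(nodes=[f"R{i}" for i in range(5)]).fit(ctrl)
            deltas = [np.abs(est.transform_subject(probe.iloc[k], str(k)).delta).max()
                      for k in range(len(probe))]
            maxes.append(np.mean(deltas))
        assert maxes[0] > maxes[1] > maxes[2]

    def test_calibration_harness_reports_both_variants(self):
        ctrl = _controls(160, 5, seed=42)
        report = null_calibration(ctrl, [f"R{i}" for i in range(5)], n_probe=25, seed=0)
        assert set(report) >= {"printed", "sqrt", "n_controls", "n_probe"}
        for variant in ("printed", "sqrt"):
            assert report[variant]["z_sd"] > 0
        # the printed form scales with (n-1), the sqrt form with sqrt(n-1)
        assert report["printed"]["z_sd"] > report["sqrt"]["z_sd"]
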