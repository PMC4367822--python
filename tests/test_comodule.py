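"""Module detection: adjacency, TOM (vs brute-force oracle), clustering,
eigengenes (vs eigendecomposition oracle), merging, membership, soft power,
transcript preselection."""

import numpy as np
import pandas as pd
import pytest

from modulome import comodule
from modulome.synthetic_data import CohortSpec, generate_cohort
from tests.conftest import tiny_block_frame


def frame_from(arr, prefix="F"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"S{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def tom_bruteforce(a):
    """Independent double-loop TOM oracle."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    p = a.shape[0]
    k = a.sum(axis=0)
    tom = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(p) if u not in (i, j))
            denom = min(k[i], k[j]) + 1 - a[i, j]
            tom[i, j] = (shared + a[i, j]) / denom if denom > 0 else 0.0
    return tom


class TestSignedAdjacency:
    @pytest.mark.parametrize("r, beta, expected", [
        (1.0, 5, 1.0),
        (-1.0, 3, 0.0),
        (0.6, 2, 0.64),
    ])
    def test_hand_values(self, r, beta, expected):
        x = np.linspace(-1, 1, 40)
        if r == 1.0:
            y = x.copy()
        elif r == -1.0:
            y = -x
        else:
            # construct exact correlation r via orthogonal decomposition
            z = np.sin(np.arange(40)) - np.mean(np.sin(np.arange(40)))
            z -= z @ x / (x @ x) * x
            y = r * x / np.std(x) + np.sqrt(1 - r**2) * z / np.std(z)
        a = comodule.signed_adjacency(frame_from(np.column_stack([x, y])), beta)
        assert a.iloc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_feature_named(self):
        frame = frame_from(np.column_stack([np.ones(10), np.arange(10)]))
        with pytest.raises(ValueError, match="F0"):
            comodule.signed_adjacency(frame, 2)


class TestTopologicalOverlap:
    def test_complete_graph_all_ones(self):
        a = pd.DataFrame(np.ones((3, 3)) - np.eye(3), columns=list("abc"),
                         index=list("abc"))
        tom = comodule.topological_overlap(a)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_empty_graph_zero_offdiagonal(self):
        a = pd.DataFrame(np.zeros((4, 4)), columns=list("abcd"),
                         index=list("abcd"))
        tom = comodule.topological_overlap(a).to_numpy()
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_three_node_hand_values(self):
        # a12 = a13 = 0.5, a23 = 0:
        #   pair (1,2): shared = a13*a32 = 0 -> (0 + 0.5)/(min(1,0.5)+1-0.5) = 0.5
        #   pair (2,3): shared = a21*a13 = 0.25 -> 0.25/(min(0.5,0.5)+1-0) = 1/6
        a = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.0], [0.5, 0.0, 0.0]])
        tom = comodule.topological_overlap(
            pd.DataFrame(a, columns=list("xyz"), index=list("xyz")))
        assert tom.loc["x", "y"] == pytest.approx(0.5, abs=1e-12)
        assert tom.loc["y", "z"] == pytest.approx(0.25 / 1.5, abs=1e-12)
        assert np.max(np.abs(tom.to_numpy() - tom_bruteforce(a))) < 1e-12

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b = rng.random((10, 10))
            a = (b + b.T) / 2
            np.fill_diagonal(a, 0.0)
            ids = [f"n{i}" for i in range(10)]
            tom = comodule.topological_overlap(
                pd.DataFrame(a, index=ids, columns=ids)).to_numpy()
            assert np.max(np.abs(tom - tom_bruteforce(a))) < 1e-12

    def test_range_and_symmetry(self, reference_cohort):
        _, logv, _, _ = reference_cohort
        tom = comodule.topological_overlap(
            comodule.signed_adjacency(logv, 6)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0
        assert np.allclose(np.diag(tom), 1.0)


class TestSelectSoftPower:
    def test_single_candidate_is_selected(self, reference_cohort):
        _, logv, _, _ = reference_cohort
        scan = comodule.select_soft_power(logv, candidates=[6])
        assert scan.selected_power == 6

    def test_mean_connectivity_decreases_in_power(self, reference_cohort):
        _, logv, _, _ = reference_cohort
        scan = comodule.select_soft_power(logv, candidates=range(1, 13))
        mc = scan.mean_connectivity
        assert (mc.diff().dropna() < 0).all()

    def test_replay_defaults_recorded(self):
        assert comodule.REPLAY_POWER_METABOLITE == 13
        assert comodule.REPLAY_POWER_TRANSCRIPT == 8

    def test_block_data_returns_finite_power(self):
        frame = tiny_block_frame(n=150, sizes=(15, 15, 15, 15), cor=0.9, seed=5)
        scan = comodule.select_soft_power(frame)
        assert scan.selected_power in list(range(1, 21))
        assert ((scan.fit_r2 >= -1) & (scan.fit_r2 <= 1)).all()


class TestClusterModules:
    def test_two_separated_blocks_recovered(self):
        d = np.ones((13, 13))
        d[:6, :6] = 0.0
        d[6:, 6:] = 0.0
        np.fill_diagonal(d, 0.0)
        ids = [f"f{i:02d}" for i in range(13)]
        out = comodule.cluster_modules(pd.DataFrame(d, index=ids, columns=ids))
        sizes = out.value_counts().to_dict()
        assert sizes == {1: 7, 2: 6}

    def test_small_branch_unassigned(self):
        d = np.ones((9, 9))
        d[:4, :4] = 0.0    # block of 4 < min size 5
        d[4:, 4:] = 0.0
        np.fill_diagonal(d, 0.0)
        ids = [f"f{i}" for i in range(9)]
        out = comodule.cluster_modules(pd.DataFrame(d, index=ids, columns=ids),
                                       min_module_size=5)
        assert (out.iloc[:4] == 0).all()
        assert (out.iloc[4:] == 1).all()

    def test_planted_modules_recovered_with_high_ari(self, reference_cohort):
        from sklearn.metrics import adjusted_rand_score

        _, logv, _, truth = reference_cohort
        mset, _ = comodule.detect_modules(logv, power=8)
        ari = adjusted_rand_score(truth.module_assignment,
                                  mset.assignment.loc[truth.module_assignment.index])
        assert ari >= 0.9

    def test_labels_invariant_to_feature_order(self, reference_cohort):
        _, logv, _, _ = reference_cohort
        rng = np.random.default_rng(1)
        shuffled = logv[rng.permutation(logv.columns)]
        a, _ = comodule.detect_modules(logv, power=8)
        b, _ = comodule.detect_modules(shuffled, power=8)
        pd.testing.assert_series_equal(
            a.assignment.sort_index(), b.assignment.sort_index())


class TestModuleEigengenes:
    def test_identical_columns_give_zscored_column(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=60)
        frame = frame_from(np.column_stack([col, col, col]))
        assignment = pd.Series(1, index=frame.columns)
        me = comodule.module_eigengenes(frame, assignment)["ME1"]
        z = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(me.to_numpy(), z, atol=1e-10)

    def test_first_pc_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            frame = frame_from(rng.normal(size=(40, 8)))
            assignment = pd.Series(1, index=frame.columns)
            me = comodule.module_eigengenes(frame, assignment)["ME1"].to_numpy()
            X = (frame - frame.mean()) / frame.std(ddof=1)
            evals, evecs = np.linalg.eigh(np.cov(X.to_numpy(), rowvar=False))
            v = evecs[:, -1]
            scores = X.to_numpy() @ v
            scores /= scores.std(ddof=1)
            assert min(np.abs(me - scores).max(),
                       np.abs(me + scores).max()) < 1e-8

    def test_orthogonal_blocks_give_uncorrelated_eigengenes(self):
        frame = tiny_block_frame(n=500, sizes=(10, 10), cor=0.8, seed=4)
        assignment = pd.Series([1] * 10 + [2] * 10, index=frame.columns)
        me = comodule.module_eigengenes(frame, assignment)
        r = np.corrcoef(me["ME1"], me["ME2"])[0, 1]
        assert abs(r) < 0.15

    def test_unit_variance_and_positive_orientation(self, reference_cohort):
        _, logv, _, truth = reference_cohort
        me = comodule.module_eigengenes(logv, truth.module_assignment)
        assert np.allclose(me.std(ddof=1), 1.0)
        kme = comodule.module_membership(logv, me)
        for m in (1, 2, 3, 4):
            members = truth.module_assignment.index[truth.module_assignment == m]
            assert kme.loc[members, f"ME{m}"].mean() > 0


class TestMergeCloseModules:
    def _two_module_frame(self, cor_between, seed=0):
        rng = np.random.default_rng(seed)
        n = 400
        L1 = rng.normal(size=n)
        L2 = cor_between * L1 + np.sqrt(1 - cor_between**2) * rng.normal(size=n)
        cols = {}
        for j in range(6):
            cols[f"A{j}"] = L1 + 0.1 * rng.normal(size=n)
        for j in range(6):
            cols[f"B{j}"] = L2 + 0.1 * rng.normal(size=n)
        frame = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        assignment = pd.Series([1] * 6 + [2] * 6, index=frame.columns)
        return frame, assignment

    def test_highly_correlated_modules_merged(self):
        frame, assignment = self._two_module_frame(0.95)
        mset = comodule.merge_close_modules(frame, assignment)
        assert len(mset.module_labels) == 1

    def test_moderately_correlated_modules_kept(self):
        frame, assignment = self._two_module_frame(0.5)
        mset = comodule.merge_close_modules(frame, assignment)
        assert len(mset.module_labels) == 2

    def test_chain_merge_matches_bruteforce_agglomeration(self):
        """Average-linkage ME merging equals a brute-force agglomeration
        oracle on a 3-module chain (A-B close, B-C close, A-C distant)."""
        rng = np.random.default_rng(6)
        n = 600
        L = rng.multivariate_normal(
            np.zeros(3),
            [[1.0, 0.8, 0.4], [0.8, 1.0, 0.8], [0.4, 0.8, 1.0]], size=n)
        cols = {}
        for b in range(3):
            for j in range(5):
                cols[f"{'ABC'[b]}{j}"] = L[:, b] + 0.05 * rng.normal(size=n)
        frame = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
        assignment = pd.Series(sum([[b + 1] * 5 for b in range(3)], []),
                               index=frame.columns)

        # oracle: repeated average-linkage agglomeration of 1 - cor(ME)
        def oracle(assign):
            assign = assign.copy()
            while True:
                labels = sorted(assign[assign != 0].unique())
                if len(labels) < 2:
                    return assign
                me = comodule.module_eigengenes(frame, assign)
                d = 1 - np.corrcoef(me.to_numpy(), rowvar=False)
                groups = {lab: [lab] for lab in labels}
                # find closest pair under average linkage (single step)
                best, pair = None, None
                for i in range(len(labels)):
                    for j in range(i + 1, len(labels)):
                        if best is None or d[i, j] < best:
                            best, pair = d[i, j], (labels[i], labels[j])
                if best >= 0.25:
                    return assign
                keep, other = pair
                assign[assign == other] = keep

        expected = comodule._canonical_labels(oracle(assignment))
        got = comodule.merge_close_modules(frame, assignment).assignment
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index(),
                                       check_names=False)


class TestModuleMembership:
    def test_single_member_module_has_unit_kme(self):
        rng = np.random.default_rng(7)
        frame = frame_from(rng.normal(size=(50, 3)))
        assignment = pd.Series([1, 0, 0], index=frame.columns)
        mset = comodule.merge_close_modules(frame, assignment)
        assert mset.kme.loc["F0", "ME1"] == pytest.approx(1.0)

    def test_anticorrelated_feature_has_minus_one(self):
        rng = np.random.default_rng(8)
        col = rng.normal(size=50)
        frame = frame_from(np.column_stack([col, -col]))
        assignment = pd.Series([1, 0], index=frame.columns)
        me = comodule.module_eigengenes(frame, assignment)
        kme = comodule.module_membership(frame, me)
        assert kme.loc["F1", "ME1"] == pytest.approx(-1.0)

    def test_own_module_membership_dominates(self, reference_cohort):
        _, logv, _, truth = reference_cohort
        me = comodule.module_eigengenes(logv, truth.module_assignment)
        kme = comodule.module_membership(logv, me)
        for m in (1, 2, 3, 4):
            members = truth.module_assignment.index[truth.module_assignment == m]
            own = kme.loc[members, f"ME{m}"].abs()
            others = kme.loc[members].drop(columns=f"ME{m}").abs().max(axis=1)
            assert (own > others).mean() > 0.95


class TestPreselectTranscripts:
    def test_transcript_mirroring_a_metabolite_selected(self, reference_cohort):
        pheno, logv, _, _ = reference_cohort
        rng = np.random.default_rng(9)
        tr = pd.DataFrame(
            {"T0": logv.iloc[:, 0] + 0.01 * rng.normal(size=len(logv))})
        out = comodule.preselect_transcripts(logv, tr, pheno)
        assert list(out) == ["T0"]

    def test_independent_transcripts_rarely_selected(self, reference_cohort):
        pheno, logv, _, _ = reference_cohort
        rng = np.random.default_rng(10)
        tr = pd.DataFrame(rng.normal(size=(len(logv), 30)),
                          index=logv.index,
                          columns=[f"T{j}" for j in range(30)])
        out = comodule.preselect_transcripts(logv, tr, pheno)
        assert len(out) == 0

    def test_weight_change_confounding_blocked_by_second_model(self):
        """A transcript linked to a metabolite only through the phenotype
        passes the age/sex model but fails the fully adjusted one."""
        spec = CohortSpec(n_samples=400, n_metabolites=5, n_transcripts=0,
                          n_modules=1, module_sizes=(5,), n_assoc_modules=1,
                          assoc_effect=0.0, mcar_rate=0, censor_rate=0,
                          batch_sd=0, seed=11)
        pheno, metab, _, _ = generate_cohort(spec)
        logv = np.log10(metab.values)
        rng = np.random.default_rng(12)
        z = (pheno["dbw"] - pheno["dbw"].mean()) / pheno["dbw"].std()
        # metabolite and transcript both driven by dbw, no direct link
        logv["MET001"] = 0.9 * z + 0.436 * rng.normal(size=len(z))
        tr = pd.DataFrame({"T0": 0.9 * z + 0.436 * rng.normal(size=len(z))},
                          index=pheno.index)
        relaxed = comodule.preselect_transcripts(logv, tr, pheno,
                                                 p_threshold=1e-3)
        assert len(relaxed) == 0
        # sanity: model A alone would have selected it
        from scipy import stats as st

        r = np.corrcoef(tr["T0"], logv["MET001"])[0, 1]
        t = r * np.sqrt((len(z) - 2) / (1 - r**2))
        assert 2 * st.t.sf(abs(t), len(z) - 2) < 1e-3


def test_full_chain_runs_quickly_on_planted_data(reference_cohort):
    """60 module features + 40 noise features: detect_modules finishes fast
    and assigns the four planted blocks."""
    import time

    _, logv, _, _ = reference_cohort
    t0 = time.time()
    mset, scan = comodule.detect_modules(logv, power=13)
    assert time.time() - t0 < 10.0
    assert len(mset.module_labels) == 4
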