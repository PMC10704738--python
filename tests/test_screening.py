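import numpy as np
import pytest

from rosscreen.ros_model import RfConfig, train
from rosscreen.screening import (
    CompartmentGrid,
    ScreeningFunnel,
    SelectionConfig,
    assign_compartment,
    funnel_report,
    funnel_text,
    screen_first_pass,
    secondary_select,
)


@pytest.fixture(scope="module")
def toy_model():
    """RF trained so predictions strongly track the first feature."""
    rng = np.random.default_rng(0)
    X = rng.uniform(-3, 3, size=(400, 3))
    y = 3.0 + X[:, 0]  # predictions straddle a 4.67 threshold
    return train(X, y, RfConfig(seed=0), selected_features=["a", "b", "c"])


def chunked(ids, X, size):
    return [(ids[i : i + size], X[i : i + size]) for i in range(0, len(ids), size)]


class TestFirstPass:
    def test_constant_low_prediction_gives_no_candidates(self, rng):
        X = rng.normal(size=(50, 2))
        model = train(X, np.full(50, 3.0), RfConfig(n_trees=5, seed=0))
        funnel = screen_first_pass([(np.arange(50).astype(str), X)], model, 4.67)
        assert funnel.n_first_pass == 0
        assert funnel.n_input == 50

    def test_chunk_invariance(self, toy_model, rng):
        n = 10_000
        X = rng.uniform(-3, 3, size=(n, 3))
        ids = np.array([f"c{i:05d}" for i in range(n)], dtype=object)
        results = {}
        for size in (1, 7, 5000, n):
            funnel = screen_first_pass(chunked(ids, X, size), toy_model, 4.67)
            results[size] = set(funnel.stage1_ids)
            assert funnel.n_input == n
        assert all(r == results[1] for r in results.values())

    def test_row_order_invariance(self, toy_model, rng):
        X = rng.uniform(-3, 3, size=(500, 3))
        ids = np.array([f"c{i}" for i in range(500)], dtype=object)
        perm = rng.permutation(500)
        a = screen_first_pass([(ids, X)], toy_model, 4.67)
        b = screen_first_pass([(ids[perm], X[perm])], toy_model, 4.67)
        assert set(a.stage1_ids) == set(b.stage1_ids)

    def test_threshold_monotonicity(self, toy_model, rng):
        X = rng.uniform(-3, 3, size=(800, 3))
        ids = np.array([f"c{i}" for i in range(800)], dtype=object)
        sizes = [
            screen_first_pass([(ids, X)], toy_model, t).n_first_pass
            for t in (3.0, 4.0, 4.67, 5.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_csv_streaming(self, toy_model, tmp_path, rng):
        X = rng.uniform(-3, 3, size=(200, 3))
        lines = ["compound_id,a,b,c"] + [
            f"c{i}," + ",".join(f"{v:.6f}" for v in X[i]) for i in range(200)
        ]
        path = tmp_path / "screen.csv"
        path.write_text("\n".join(lines) + "\n")
        from_file = screen_first_pass(path, toy_model, 4.67, chunk_size=33)
        ids = np.array([f"c{i}" for i in range(200)], dtype=object)
        in_memory = screen_first_pass([(ids, X)], toy_model, 4.67)
        assert set(from_file.stage1_ids) == set(in_memory.stage1_ids)


class TestCompartments:
    def test_corner_convention(self):
        ids = assign_compartment(np.array([[-1.0, -1.0], [1.0, 1.0]]))
        assert ids.tolist() == [0, 63]

    def test_origin_cell(self):
        # 0 falls in [0, 0.25) on both axes -> column 4, row 4 -> id 36
        assert assign_compartment(np.array([[0.0, 0.0]]))[0] == 36

    def test_matches_bruteforce_interval_search(self, rng):
        pts = rng.uniform(-1, 1, size=(10_000, 2))
        ids = assign_compartment(pts)
        edges = np.linspace(-1, 1, 9)
        for n in range(len(pts)):
            x, y = pts[n]
            col = next(
                j for j in range(8)
                if (edges[j] <= x < edges[j + 1]) or (j == 7 and x == 1.0)
            )
            row = next(
                j for j in range(8)
                if (edges[j] <= y < edges[j + 1]) or (j == 7 and y == 1.0)
            )
            assert ids[n] == row * 8 + col
        assert set(ids.tolist()) == set(range(64))  # 10^4 uniform points fill all cells

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        pts = rng.uniform(-1, 1, size=(2000, 2))
        ids = assign_compartment(pts)
        assert np.all((ids >= 0) & (ids < 64))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of"):
            assign_compartment(np.array([[1.5, 0.0]]))


def exhaustive_selection_oracle(ids, coords, preds, refs, quota):
    """Independent re-derivation of the rank-sum selection via explicit loops."""
    grid_edges = np.linspace(-1, 1, 9)

    def cell_of(p):
        col = min(int((p[0] + 1) / 0.25), 7)
        row = min(int((p[1] + 1) / 0.25), 7)
        return row * 8 + col

    ref_cells = {cell_of(r) for r in refs}
    selected = []
    for cell in sorted(ref_cells):
        members = [i for i in range(len(ids)) if cell_of(coords[i]) == cell]
        if not members:
            continue
        dist = {
            i: min(np.linalg.norm(coords[i] - r) for r in refs) for i in members
        }
        scores = {}
        for i in members:
            rank_d = 1 + sum(dist[j] < dist[i] for j in members)
            rank_p = 1 + sum(preds[j] > preds[i] for j in members)
            scores[i] = rank_d + rank_p
        order = sorted(members, key=lambda i: (scores[i], -preds[i], str(ids[i])))
        selected.extend(ids[i] for i in order[:quota])
    return selected


class TestSecondarySelection:
    @pytest.fixture()
    def instance(self, rng):
        ids = np.array([f"c{i:02d}" for i in range(50)], dtype=object)
        coords = rng.uniform(-1, 1, size=(50, 2))
        preds = rng.uniform(4.0, 6.0, size=50)
        refs = rng.uniform(-1, 1, size=(5, 2))
        return ids, coords, preds, refs

    def test_matches_exhaustive_oracle(self, instance):
        ids, coords, preds, refs = instance
        for quota in (1, 3, 10):
            selected, _ = secondary_select(
                ids, coords, preds, refs,
                config=SelectionConfig(per_compartment_quota=quota),
            )
            assert selected == exhaustive_selection_oracle(
                ids, coords, preds, refs, quota
            )

    def test_colocated_max_prediction_candidate_first(self):
        refs = np.array([[0.1, 0.1]])
        ids = np.array(["winner", "far", "low"], dtype=object)
        coords = np.array([[0.1, 0.1], [0.2, 0.2], [0.12, 0.12]])
        preds = np.array([6.0, 5.5, 5.0])
        selected, detail = secondary_select(ids, coords, preds, refs)
        assert selected[0] == "winner"
        row = detail[detail.compound_id == "winner"].iloc[0]
        assert row.rank_d == 1 and row.rank_p == 1

    def test_zero_quota_empty(self, instance):
        ids, coords, preds, refs = instance
        selected, _ = secondary_select(
            ids, coords, preds, refs, config=SelectionConfig(per_compartment_quota=0)
        )
        assert selected == []

    def test_quota_monotonicity(self, instance):
        ids, coords, preds, refs = instance
        sizes = [
            len(secondary_select(ids, coords, preds, refs,
                                 config=SelectionConfig(per_compartment_quota=q))[0])
            for q in (0, 1, 2, 5, 50)
        ]
        assert sizes == sorted(sizes)

    def test_excluded_never_selected(self, instance):
        ids, coords, preds, refs = instance
        all_sel, _ = secondary_select(
            ids, coords, preds, refs, config=SelectionConfig(per_compartment_quota=50)
        )
        banned = frozenset(str(c) for c in all_sel[:3])
        selected, _ = secondary_select(
            ids, coords, preds, refs,
            config=SelectionConfig(per_compartment_quota=50, exclude_ids=banned),
        )
        assert not banned & {str(c) for c in selected}

    def test_empty_reference_set_rejected(self, instance):
        ids, coords, preds, _ = instance
        with pytest.raises(ValueError, match="empty reference"):
            secondary_select(ids, coords, preds, np.empty((0, 2)))

    def test_global_cap(self, instance):
        ids, coords, preds, refs = instance
        selected, _ = secondary_select(
            ids, coords, preds, refs,
            config=SelectionConfig(per_compartment_quota=10, global_cap=4),
        )
        assert len(selected) <= 4


class TestFunnelReport:
    def test_counts_match_id_sets(self, toy_model, rng):
        X = rng.uniform(-3, 3, size=(300, 3))
        ids = np.array([f"c{i}" for i in range(300)], dtype=object)
        funnel = screen_first_pass([(ids, X)], toy_model, 4.67)
        report = funnel_report(funnel)
        assert report["first_pass_candidates"] == len(funnel.stage1_ids)
        assert report["total_screened"] == 300

    def test_stage2_absent_not_zero(self):
        funnel = ScreeningFunnel(n_input=10, stage1_ids=["a"], threshold=4.67)
        report = funnel_report(funnel)
        assert "second_pass_candidates" not in report
        assert "(not run)" in funnel_text(funnel)

    def test_nestedness_after_stage2(self, rng):
        from rosscreen.screening import apply_secondary

        ids = np.array([f"c{i}" for i in range(40)], dtype=object)
        funnel = ScreeningFunnel(
            n_input=100,
            stage1_ids=list(ids),
            stage1_predictions={c: 5.0 for c in ids},
            threshold=4.67,
        )
        coords = rng.uniform(-1, 1, size=(40, 2))
        refs = rng.uniform(-1, 1, size=(4, 2))
        funnel = apply_secondary(funnel, coords, refs)
        assert set(funnel.stage2_ids) <= set(funnel.stage1_ids)
        assert funnel.n_second_pass <= funnel.n_first_pass <= funnel.n_input
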