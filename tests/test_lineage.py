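import numpy as np
import pandas as pd
import pytest

from blastula.lineage import (
    CellTrack,
    LineageError,
    LineageTree,
    assign_generations_and_types,
    contact_degrees,
    embryo_curves,
    extract_features,
    read_lineage,
    write_lineage,
)
from blastula.simulator import simulate, to_tree


def track(cid, mother, times, vol=None, surf=None, label=None, pos=None):
    times = np.asarray(times, dtype=float)
    n = len(times)
    return CellTrack(
        cell_id=cid,
        mother_id=mother,
        times=times,
        positions=np.zeros((n, 3)) if pos is None else np.asarray(pos, dtype=float),
        volumes=None if vol is None else np.full(n, float(vol)),
        surfaces=None if surf is None else np.full(n, float(surf)),
        type_label=label,
    )


@pytest.fixture
def toy_tree():
    # mother m lives t=0..4, divides; daughters d1, d2 live t=6..10
    return LineageTree(
        [
            track("m", None, [0, 2, 4], vol=100.0, surf=50.0, label="Mac"),
            track("d1", "m", [6, 8, 10], vol=50.0, surf=30.0, label="Mac"),
            track("d2", "m", [6, 8, 10], vol=50.0, surf=30.0, label="Mac"),
        ],
        roots_born_at_start=True,
    )


TOY_FILE = """# time_unit: min
cell_id\tmother_id\tt\tx\ty\tz\ttype\tvolume\tsurface
m\t\t0\t0\t0\t0\tMac\t100\t50
m\t\t2\t0\t0\t0\tMac\t100\t50
d1\tm\t4\t0\t0\t0\tMac\t50\t30
d1\tm\t6\t0\t0\t0\tMac\t50\t30
d2\tm\t4\t1\t0\t0\tMac\t50\t30
d2\tm\t6\t1\t0\t0\tMac\t50\t30
"""


class TestIO:
    def test_minimal_tree(self, tmp_path):
        p = tmp_path / "toy.tsv"
        p.write_text(TOY_FILE)
        tree = read_lineage(p)
        assert len(tree) == 3
        assert tree.divisions == {"m": ("d1", "d2")}

    def test_round_trip_identity(self, tmp_path, small_model):
        tree = to_tree(simulate(small_model, seed=4), step=2.0)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_lineage(tree, p1)
        write_lineage(read_lineage(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_three_daughters_rejected(self):
        with pytest.raises(LineageError, match="3 daughters"):
            LineageTree(
                [
                    track("m", None, [0, 2]),
                    track("a", "m", [4]),
                    track("b", "m", [4]),
                    track("c", "m", [4]),
                ]
            )

    def test_missing_mother_rejected(self):
        with pytest.raises(LineageError, match="missing mother"):
            LineageTree([track("a", "ghost", [0])])

    def test_non_contiguous_track_rejected(self):
        with pytest.raises(LineageError, match="not contiguous"):
            LineageTree([track("a", None, [0, 2, 8])])

    def test_daughter_not_after_mother_rejected(self):
        with pytest.raises(LineageError):
            LineageTree(
                [
                    track("m", None, [0, 2, 4]),
                    track("a", "m", [4]),
                    track("b", "m", [4]),
                ]
            )

    def test_negative_volume_rejected(self):
        tr = track("a", None, [0, 2], vol=10.0)
        tr.volumes[1] = -5.0
        with pytest.raises(LineageError, match="non-positive volume"):
            LineageTree([tr])

    def test_hpf_conversion(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(TOY_FILE.replace("# time_unit: min", "# time_unit: hpf"))
        tree = read_lineage(p)
        assert tree.tracks["m"].times[1] == pytest.approx(120.0)


class TestGenerations:
    def test_chain_increments(self):
        tree = LineageTree(
            [
                track("r", None, [0, 2], label="Mes"),
                track("a", "r", [4, 6]),
                track("b", "r", [4, 6]),
                track("aa", "a", [8]),
                track("ab", "a", [8]),
            ]
        )
        assign_generations_and_types(tree, root_generation=6)
        assert tree.tracks["r"].generation == 6
        assert tree.tracks["a"].generation == 7
        assert tree.tracks["aa"].generation == 8

    def test_label_propagation(self, toy_tree):
        assign_generations_and_types(toy_tree)
        assert all(tr.type_label == "Mac" for tr in toy_tree.tracks.values())

    def test_distinct_roots_keep_labels(self):
        tree = LineageTree(
            [
                track("r1", None, [0], label="Mes"),
                track("r2", None, [0], label="SMic"),
                track("a", "r1", [2]),
                track("b", "r1", [2]),
                track("c", "r2", [2]),
                track("d", "r2", [2]),
            ]
        )
        assign_generations_and_types(tree)
        assert tree.tracks["a"].type_label == "Mes"
        assert tree.tracks["c"].type_label == "SMic"

    def test_unlabelled_root_rejected(self):
        tree = LineageTree([track("r", None, [0])])
        with pytest.raises(LineageError, match="unlabelled root"):
            assign_generations_and_types(tree)


class TestFeatures:
    def test_constant_volume_average(self, toy_tree):
        assign_generations_and_types(toy_tree)
        f = extract_features(toy_tree)
        assert f.loc["m", "v"] == pytest.approx(100.0)

    def test_daughter_mother_ratio(self, toy_tree):
        # extend daughters so their cycles complete
        tree = LineageTree(
            [
                track("m", None, [0, 2], vol=100.0, label="Mac"),
                track("d1", "m", [4, 6], vol=50.0),
                track("d2", "m", [4, 6], vol=80.0),
                track("g1", "d1", [8]),
                track("g2", "d1", [8]),
                track("g3", "d2", [8]),
                track("g4", "d2", [8]),
            ],
            roots_born_at_start=True,
        )
        assign_generations_and_types(tree)
        f = extract_features(tree)
        assert f.loc["d1", "a"] == pytest.approx(0.5)
        assert f.loc["d2", "a"] == pytest.approx(0.8)

    def test_truncated_cycle_excluded(self, toy_tree):
        # roots_born_at_start=False: the mother's cycle start is unobserved
        tree = LineageTree(
            [tr for tr in toy_tree.copy().tracks.values()], roots_born_at_start=False
        )
        assign_generations_and_types(tree)
        f = extract_features(tree)
        assert not f.loc["m", "complete"]
        assert np.isnan(f.loc["m", "x"])

    def test_leaf_cycles_incomplete(self, toy_tree):
        assign_generations_and_types(toy_tree)
        f = extract_features(toy_tree)
        assert not f.loc["d1", "complete"]  # division never observed

    def test_filiation_consistency(self, small_model):
        tree = to_tree(simulate(small_model, seed=9, terminal_stubs=True))
        assign_generations_and_types(tree)
        f = extract_features(tree)
        done = f[f["complete"] & f["mother_id"].notna()]
        mothers = f.loc[done["mother_id"]]
        ok = mothers["complete"].to_numpy()
        np.testing.assert_allclose(
            done["m"].to_numpy()[ok],
            mothers["m"].to_numpy()[ok] + done["x"].to_numpy()[ok],
        )

    def test_zero_noise_features_exact(self, zero_noise_model):
        tree = to_tree(simulate(zero_noise_model, seed=0, terminal_stubs=True), step=2.0)
        f = extract_features(tree)
        done = f[f["complete"]]
        gen7 = done[done["generation"] == 7]
        assert set(gen7["x"]) == {44.0}
        assert set(done[done["generation"] == 6]["m"]) == {44.0}
        gen8 = done[done["generation"] == 8]
        assert np.allclose(gen8["a"].dropna(), 0.5)
        assert np.allclose(
            done[done["generation"] == 6]["v"], 2048.0
        )


class TestCurves:
    def test_single_division_step(self):
        tree = LineageTree(
            [
                track("m", None, [0, 2, 4, 6, 8], vol=100.0, label="Mes"),
                track("a", "m", [10, 12], vol=50.0, label="Mes"),
                track("b", "m", [10, 12], vol=50.0, label="Mes"),
            ]
        )
        cur = embryo_curves(tree)
        n_at = dict(zip(cur.times, cur.n))
        assert n_at[8] == 1 and n_at[10] == 2

    def test_total_volume(self, toy_tree):
        cur = embryo_curves(toy_tree)
        assert cur.w[0] == pytest.approx(100.0)
        assert cur.w[-1] == pytest.approx(100.0)  # 2 x 50 after division

    def test_partition_property(self, small_model):
        tree = to_tree(simulate(small_model, seed=11))
        cur = embryo_curves(tree)
        for key in ("n", "w", "z"):
            total = sum(c[key] for c in cur.per_type.values())
            np.testing.assert_allclose(total, getattr(cur, key))

    def test_n_non_decreasing_inside_window(self, small_model):
        tree = to_tree(simulate(small_model, seed=12))
        cur = embryo_curves(tree)
        assert np.all(np.diff(cur.n) >= 0)


class TestDegrees:
    def test_two_touching(self, toy_tree):
        df = contact_degrees(toy_tree, {0.0: [("m", "m")], 2.0: []})
        # self-contact is pathological input; use a 2-cell time instead
        df = contact_degrees(toy_tree, {6.0: [("d1", "d2")]})
        d = df.set_index("cell_id")["degree"]
        assert d["d1"] == 1 and d["d2"] == 1

    def test_isolated_cell(self, toy_tree):
        df = contact_degrees(toy_tree, {0.0: []})
        assert df.set_index("cell_id")["degree"]["m"] == 0

    def test_symmetry(self, toy_tree):
        a = contact_degrees(toy_tree, {6.0: [("d1", "d2")]})
        b = contact_degrees(toy_tree, {6.0: [("d2", "d1")]})
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_cell_rejected(self, toy_tree):
        with pytest.raises(LineageError, match="unknown cell"):
            contact_degrees(toy_tree, {6.0: [("d1", "nope")]})
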