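"""Figure construction: 3D scatters, lineage-tree layout/rendering, export."""

import xml.etree.ElementTree as ET

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pytest

from wormtrace import (SimulationParams, StyleSpec, build_tree_layout,
                       export_figure, plot3d, render_tree, select_cells,
                       simulate_embryo, tree_segments)

from conftest import make_table, rowd


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


def four_cell_table():
    rows = [rowd(c, 1, x=float(i), y=float(-i), z=float(i % 2), blot=float(50 * i))
            for i, c in enumerate(["ABa", "ABp", "EMS", "P2"])]
    return make_table(rows, units="micron")


class TestPlot3D:
    def test_marker_per_cell(self):
        fig = plot3d(four_cell_table(), 1)
        counts = sum(len(c.get_offsets()) for c in fig.axes[0].collections)
        assert counts == 4

    def test_time_absent(self):
        with pytest.raises(ValueError, match="99"):
            plot3d(four_cell_table(), 99)

    def test_clamping_to_color_max(self):
        t = four_cell_table()
        style = StyleSpec(color_min=0.0, color_max=100.0)
        fig = plot3d(t, 1, style)
        coll = fig.axes[0].collections[0]
        vals = coll.get_array()
        assert vals.max() <= 100.0  # 150 clamped, not overflowed
        # the over-max cell renders at exactly the max color
        cmap, norm = coll.cmap, coll.norm
        assert np.allclose(cmap(norm(150.0)), cmap(norm(100.0)))

    def test_highlight_matches_select_cells(self, sim_default):
        acq, _ = sim_default
        style = StyleSpec(highlight=(("Cxp", "^", "red"),))
        fig = plot3d(acq, 20, style)
        expected = select_cells(acq, ["Cxp"], include_descendants=False)
        present = set(acq.at_time(20)["cell"].astype(str)) & expected
        highlight_coll = fig.axes[0].collections[-1]
        assert len(highlight_coll.get_offsets()) == len(present) > 0


class TestTreeLayout:
    def test_single_cell_no_divisions(self):
        t = make_table([rowd("MSa", tt) for tt in (3, 4, 5)], expr_columns=())
        layout = build_tree_layout(t, "MSa")
        assert set(layout.x) == {"MSa"}
        assert layout.span["MSa"] == (3.0, 5.0)

    def test_parent_midpoint_rule(self):
        rows = [rowd("MSa", tt) for tt in (1, 2)]
        rows += [rowd("MSaa", tt, x=1.0) for tt in (3, 4)]
        rows += [rowd("MSap", tt, x=-1.0) for tt in (3, 4)]
        t = make_table(rows, expr_columns=())
        layout = build_tree_layout(t, "MSa")
        assert len(layout.x) == 3
        kids_x = [layout.x["MSaa"], layout.x["MSap"]]
        assert layout.x["MSa"] == pytest.approx((min(kids_x) + max(kids_x)) / 2)
        assert layout.x["MSaa"] < layout.x["MSap"]  # canonical a < p

    def test_root_never_observed(self):
        t = make_table([rowd("ABa", 1)], expr_columns=())
        with pytest.raises(ValueError, match="never observed"):
            build_tree_layout(t, "MSa")

    def test_tracking_gap_bridged(self):
        """A missing intermediate generation attaches grandchildren to the
        nearest observed ancestor."""
        rows = [rowd("C", 1), rowd("Caa", 3), rowd("Cap", 3)]
        t = make_table(rows, expr_columns=())
        layout = build_tree_layout(t, "C")
        assert set(layout.children["C"]) == {"Caa", "Cap"}

    @staticmethod
    def _check_invariants(layout):
        def subtree_leaves(cell):
            kids = layout.children.get(cell, [])
            if not kids:
                return {cell}
            out = set()
            for k in kids:
                out |= subtree_leaves(k)
            return out

        for parent, kids in layout.children.items():
            if len(kids) < 2:
                continue
            xs = [layout.x[k] for k in kids]
            assert layout.x[parent] == pytest.approx((min(xs) + max(xs)) / 2)
            intervals = []
            for k in kids:
                lx = [layout.x[c] for c in subtree_leaves(k)]
                intervals.append((min(lx), max(lx)))
            intervals.sort()
            for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
                assert hi < lo  # sibling subtrees occupy disjoint x ranges

    def test_invariants_deep_lineage(self):
        """Simulated lineage to depth 10: disjoint sibling intervals,
        midpoint parents, leaf count = observed terminal cells."""
        import wormtrace.synthetic as syn
        sched = syn.default_schedule({"AB": 10}, t_end=40,
                                     first_division={"AB": 4}, periods={"AB": 3})
        params = SimulationParams(
            schedule=sched, t_end=40, canonicalize=False,
            orientation=(np.eye(3), np.zeros(3)),
            noise_sigma=0.0, position_jitter_sigma=0.0,
        )
        table, truth = simulate_embryo(params, seed=0)
        layout = build_tree_layout(table, "AB")
        self._check_invariants(layout)
        terminal = {c for c in layout.x
                    if not any(k in layout.x for k in layout.children.get(c, []))}
        assert set(layout.leaves) == terminal
        deepest = max(len(c) - 2 for c in layout.x)  # suffix length under AB
        assert deepest == 10

    def test_leaf_count_oracle(self, sim_default):
        acq, truth = sim_default
        layout = build_tree_layout(acq, "MS")
        observed = set(layout.x)
        expected_leaves = {
            c for c in observed
            if not any(d in observed for d in
                       [c + letter for letter in "aplrdv"])
        }
        assert set(layout.leaves) == expected_leaves


class TestRenderTree:
    def test_segment_count_equals_rows(self, sim_default):
        acq, _ = sim_default
        layout = build_tree_layout(acq, "MS", 7, 30)
        segs = tree_segments(layout, acq)
        in_window = acq.data[
            (acq.data["time"] >= 7) & (acq.data["time"] <= 30)
            & acq.data["cell"].astype(str).isin(layout.x)
        ]
        assert len(segs) == len(in_window)

    def test_svg_well_formed(self, sim_default, tmp_path):
        acq, _ = sim_default
        layout = build_tree_layout(acq, "MS")
        fig = render_tree(layout, acq)
        path = export_figure(fig, tmp_path / "tree.svg")
        root = ET.parse(path).getroot()
        assert root.tag.endswith("svg")

    def test_constant_expression_single_color(self):
        rows = [rowd("MSa", tt, blot=42.0) for tt in (1, 2, 3)]
        t = make_table(rows)
        layout = build_tree_layout(t, "MSa")
        fig = render_tree(layout, t)
        lc = fig.axes[0].collections[0]
        colors = lc.get_colors()
        assert np.allclose(colors, colors[0])

    def test_missing_column_monochrome_warns(self):
        t = make_table([rowd("MSa", 1)], expr_columns=())
        layout = build_tree_layout(t, "MSa")
        with pytest.warns(UserWarning, match="monochrome"):
            fig = render_tree(layout, t, "blot")
        assert len(fig.axes[0].collections) >= 1


class TestExport:
    def test_png_magic_bytes(self, tmp_path):
        fig = plot3d(four_cell_table(), 1)
        path = export_figure(fig, tmp_path / "fig.png")
        assert path.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_unsupported_format(self, tmp_path):
        fig, _ = plt.subplots()
        with pytest.raises(ValueError, match="unsupported"):
            export_figure(fig, tmp_path / "fig.bmp")

    def test_deterministic_dimensions(self, tmp_path):
        from PIL import Image
        fig = plot3d(four_cell_table(), 1)
        p1 = export_figure(fig, tmp_path / "a.png", width=640, height=480)
        p2 = export_figure(fig, tmp_path / "b.png", width=640, height=480)
        assert Image.open(p1).size == Image.open(p2).size == (640, 480)

    def test_batch_export_names(self, tmp_path, rng):
        from wormtrace import random_table
        for i in range(3):
            t = random_table(rng, embryo_id=f"e{i}")
            t = t.with_data(t.data, units="micron")
            fig = plot3d(t, int(t.data["time"].iloc[0]))
            export_figure(fig, tmp_path / f"{t.embryo_id}.svg")
            plt.close(fig)
        assert sorted(p.name for p in tmp_path.glob("*.svg")) == [
            "e0.svg", "e1.svg", "e2.svg"]
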