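import numpy as np
import pandas as pd
import pytest

from wavescan.detect import ParameterBox
from wavescan.diagrams import (AUCDiagram2D, auc_diagram_2d, auc_diagram_3d,
                               best_cell, diagram_to_frame, refine,
                               render_diagram, render_diagram_3d)
from wavescan.stats import roc_auc

from conftest import make_event_frame, make_roster


def random_cohort_events(rng, n_pat=6, n_ctl=5, rate_pat=1.0, rate_ctl=1.0,
                         frange=(1.0, 10.0), duration=90.0):
    rows = []
    roster = []
    for group, n, rate in (("patient", n_pat, rate_pat),
                           ("control", n_ctl, rate_ctl)):
        for i in range(n):
            sid = f"{group}{i}"
            roster.append((sid, group))
            k = rng.poisson(rate * duration)
            for f in rng.uniform(*frange, k):
                rows.append((sid, group, f, rng.uniform(5, 50),
                             rng.uniform(0.5, 5), rng.uniform(1, 8)))
    return make_event_frame(rows), make_roster(roster, duration)


GRIDS = {"frequency": (1.0, 20.0, 1.0), "psd": (0.0, 100.0, 10.0),
         "duration": (0.0, 6.0, 0.5), "bandwidth": (0.0, 10.0, 1.0)}


class Test2D:
    def test_identical_event_streams_give_all_half(self, rng):
        rows = [(f"{g}{i}", g, f, 10.0, 2.0, 3.0)
                for g in ("patient", "control") for i in range(4)
                for f in (3.0, 7.5, 12.0)]
        events = make_event_frame(rows)
        roster = make_roster([(f"{g}{i}", g) for g in ("patient", "control")
                              for i in range(4)])
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS)
        assert np.all(d.auc[d.defined] == 0.5)

    def test_triangular_support_and_diagonal_included(self, rng):
        events, roster = random_cohort_events(rng)
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS)
        low = d.lower_bounds[:, None]
        up = d.upper_bounds[None, :]
        np.testing.assert_array_equal(d.defined, low <= up)
        assert d.defined.diagonal().all()

    def test_group_relabel_mirrors_auc(self, rng):
        events, roster = random_cohort_events(rng, rate_pat=1.5)
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS)
        swapped = auc_diagram_2d(events, roster, "frequency", grids=GRIDS,
                                 groups=("control", "patient"))
        np.testing.assert_allclose(d.auc[d.defined] + swapped.auc[d.defined],
                                   1.0, atol=1e-12)

    def test_constraints_apply_to_other_parameters_only(self, rng):
        events, roster = random_cohort_events(rng)
        box = ParameterBox(min_psd=25.0, min_freq=9.0, max_freq=9.5)
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS,
                           constraints=box)
        # frequency cells outside the box's own frequency bounds still defined
        assert d.defined[0, -1]

    def test_subjects_without_events_count_as_zero_rate(self):
        rows = [("patient0", "patient", 5.0, 10.0, 2.0, 3.0)] * 10
        events = make_event_frame(rows)
        roster = make_roster([("patient0", "patient"), ("patient1", "patient"),
                              ("control0", "control"), ("control1", "control")])
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS)
        i = np.flatnonzero(d.lower_bounds == 5.0)[0]
        assert d.auc[i, i] == 0.75   # one patient above both controls, one tied

    def test_unknown_parameter_rejected(self, rng):
        events, roster = random_cohort_events(rng)
        with pytest.raises(ValueError):
            auc_diagram_2d(events, roster, "kurtosis")

    def test_too_few_subjects_rejected(self, rng):
        events, roster = random_cohort_events(rng, n_pat=1)
        with pytest.raises(ValueError):
            auc_diagram_2d(events, roster, "frequency", grids=GRIDS)


class Test3D:
    def test_slices_match_independent_2d_diagrams(self, rng):
        events, roster = random_cohort_events(rng, rate_pat=1.4)
        d3 = auc_diagram_3d(events, roster, "frequency", prange=(1.0, 10.0),
                            resolutions=[1, 4, 7])
        for s in d3.slices:
            edges = np.linspace(1.0, 10.0, s.resolution + 1)
            d2 = auc_diagram_2d(events, roster, "frequency",
                                lower_bounds=edges[:-1],
                                upper_bounds=edges[1:],
                                min_width=(9.0 / s.resolution) * (1 - 1e-9),
                                compute_p=True)
            np.testing.assert_array_equal(s.diagram.auc, d2.auc)
            np.testing.assert_array_equal(s.diagram.p, d2.p)

    def test_cell_count_is_triangular_number(self, rng):
        events, roster = random_cohort_events(rng)
        d3 = auc_diagram_3d(events, roster, "frequency", resolutions=[5])
        assert int(d3.slices[0].diagram.defined.sum()) == 15

    def test_single_resolution_cell_equals_whole_range_comparison(self, rng):
        events, roster = random_cohort_events(rng, rate_pat=2.0)
        d3 = auc_diagram_3d(events, roster, "frequency", prange=(1.0, 10.0),
                            resolutions=[1])
        cell = d3.slices[0].diagram.auc[0, 0]
        rates = {}
        for sid, sub in events.groupby("subject_id"):
            n = ((sub.f_central_hz >= 1.0) & (sub.f_central_hz <= 10.0)).sum()
            rates[sid] = n / 90.0
        pats = [rates.get(r.subject_id, 0) for r in
                roster[roster.group == "patient"].itertuples()]
        ctls = [rates.get(r.subject_id, 0) for r in
                roster[roster.group == "control"].itertuples()]
        assert abs(cell - roc_auc(pats, ctls)) < 1e-12

    def test_strong_effect_unmasks_cells_null_does_not(self, rng):
        strong, roster = random_cohort_events(rng, n_pat=10, n_ctl=10,
                                              rate_pat=3.0, rate_ctl=0.5)
        d3 = auc_diagram_3d(strong, roster, "frequency", resolutions=range(1, 9))
        assert any(s.significant.any() for s in d3.slices)
        alphas = [s.alpha_b for s in d3.slices]
        assert all(a1 > a2 for a1, a2 in zip(alphas, alphas[1:]))


class TestBestCellAndRefine:
    def _diagram(self, auc):
        n = auc.shape[0]
        bounds = np.arange(1.0, n + 1.0)
        return AUCDiagram2D(parameter="frequency", lower_bounds=bounds,
                            upper_bounds=bounds.copy(), auc=auc, n_patients=5,
                            n_controls=5, constraints=ParameterBox())

    def test_all_half_returns_full_range(self):
        auc = np.full((5, 5), np.nan)
        auc[np.triu_indices(5)] = 0.5
        cell = best_cell(self._diagram(auc))
        assert (cell.lower, cell.upper, cell.auc) == (1.0, 5.0, 0.5)

    def test_single_extreme_cell_wins(self):
        auc = np.full((5, 5), np.nan)
        auc[np.triu_indices(5)] = 0.5
        auc[1, 3] = 0.9
        cell = best_cell(self._diagram(auc))
        assert (cell.lower, cell.upper, cell.auc) == (2.0, 4.0, 0.9)

    def test_score_tie_broken_by_width_then_lower_bound(self):
        auc = np.full((5, 5), np.nan)
        auc[np.triu_indices(5)] = 0.5
        auc[2, 2] = 0.1      # |0.4|, width 0
        auc[1, 4] = 0.9      # |0.4|, width 3 -> wins
        cell = best_cell(self._diagram(auc))
        assert (cell.lower, cell.upper, cell.auc) == (2.0, 5.0, 0.9)

    def test_identical_streams_stop_immediately(self):
        rows = [(f"{g}{i}", g, f, 10.0, 2.0, 3.0)
                for g in ("patient", "control") for i in range(3)
                for f in (3.0, 7.0)]
        events = make_event_frame(rows)
        roster = make_roster([(f"{g}{i}", g) for g in ("patient", "control")
                              for i in range(3)])
        state = refine(events, roster, grids=GRIDS)
        assert state.stop_reason == "no_change"
        assert len(state.history) == 1
        assert state.box == ParameterBox()

    def test_band_effect_refined_to_overlapping_bounds(self, rng):
        # patient excess only in 8-14 Hz over a shared background: the
        # refined frequency interval must stay inside the grid, overlap the
        # injected band, and improve on the whole-range comparison
        rows = []
        roster = []
        for group, n, rate in (("patient", 8, 0.6), ("control", 8, 0.2)):
            for i in range(n):
                sid = f"{group}{i}"
                roster.append((sid, group))
                mult = rng.lognormal(0, 0.4)
                for f in rng.uniform(8.0, 14.0, rng.poisson(rate * mult * 90)):
                    rows.append((sid, group, f, 30.0, 2.0, 3.0))
                bg = rng.poisson(0.6 * rng.lognormal(0, 0.4) * 90)
                for f in rng.uniform(1.0, 20.0, bg):
                    rows.append((sid, group, f, 30.0, 2.0, 3.0))
        events = make_event_frame(rows)
        state = refine(events, make_roster(roster), grids=GRIDS)
        assert state.stop_reason in {"no_change", "degraded", "max_iter"}
        assert state.box.min_freq >= 1.0 and state.box.max_freq <= 20.0
        assert state.box.min_freq <= 14.0 and state.box.max_freq >= 8.0
        applied = [h for h in state.history if h["action"] == "apply"]
        assert applied
        assert applied[-1]["score"] > state.history[0]["previous_score"]

    def test_refinement_deterministic(self, rng):
        events, roster = random_cohort_events(rng, rate_pat=1.6)
        a = refine(events, roster, grids=GRIDS)
        b = refine(events, roster, grids=GRIDS)
        assert a == b


class TestExport:
    def test_long_frame_and_renders(self, rng, tmp_path):
        events, roster = random_cohort_events(rng, rate_pat=1.5)
        d = auc_diagram_2d(events, roster, "frequency", grids=GRIDS,
                           compute_p=True)
        frame = diagram_to_frame(d)
        assert set(frame.columns) == {"parameter", "lower", "upper",
                                      "resolution", "auc", "p", "alpha_b",
                                      "significant"}
        assert len(frame) == int(d.defined.sum())
        png = tmp_path / "d.png"
        render_diagram(d, png)
        assert png.stat().st_size > 0
        d3 = auc_diagram_3d(events, roster, "frequency", resolutions=[2, 4])
        png3 = tmp_path / "d3.png"
        render_diagram_3d(d3, png3)
        assert png3.stat().st_size > 0
        f3 = diagram_to_frame(d3)
        assert sorted(f3.resolution.unique()) == [2, 4]
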