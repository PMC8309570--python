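"""AUC range-scan diagrams and the iterative parameter-refinement loop.

A 2D AUC diagram scans, for one wave-train parameter, every (lower bound,
upper bound) range on a grid: the cell (low, up) holds the area under the
ROC curve comparing per-subject wave-train rates (events inside the closed
range, restricted by the constraints on the other three parameters)
between patients and controls. Cells with low > up are undefined, giving
the triangular shape; the diagonal (low = up) is included.

The 3D AUC diagram stacks such scans over diagram resolutions R: the
parameter range is partitioned into R equal bins, bounds are the bin edges
(C = R(R+1)/2 cells), and each cell additionally carries a Mann-Whitney
p-value. Cells with p above the Sidak-corrected level alpha_B(R) are masked
out, so the surviving stack is the isosurface data of significant ranges
across scales.

``refine`` automates the analyst's loop: build all four diagrams, take the
cell with the most pronounced deviation from AUC = 0.5, constrain that
parameter to the cell's range, and repeat until nothing improves (or the
best achievable AUC degrades, meaning the selection became too narrow).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import ParameterBox
from .stats import auc_matrix, bonferroni_alpha, correction_count, mwu_p_matrix

PARAMETERS = ("frequency", "psd", "duration", "bandwidth")
PARAM_COLUMN = {"frequency": "f_central_hz", "psd": "psd_max",
                "duration": "duration_periods", "bandwidth": "bandwidth_hz"}
PARAM_BOUNDS = {"frequency": ("min_freq", "max_freq"),
                "psd": ("min_psd", "max_psd"),
                "duration": ("min_durat", "max_durat"),
                "bandwidth": ("min_bandwidth", "max_bandwidth")}
# default scan grids: (start, stop, step)
DEFAULT_GRIDS = {"frequency": (1.0, 50.0, 1.0), "psd": (0.0, 1000.0, 10.0),
                 "duration": (0.0, 10.0, 0.1), "bandwidth": (0.0, 50.0, 0.1)}
_TOL = 1e-9


def grid_bounds(parameter: str, grids: Mapping = DEFAULT_GRIDS) -> np.ndarray:
    start, stop, step = grids[parameter]
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class AUCDiagram2D:
    parameter: str
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    auc: np.ndarray                   # (n_lower, n_upper), NaN where undefined
    n_patients: int
    n_controls: int
    constraints: ParameterBox
    min_width: float = 0.0
    p: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.auc)


@dataclass(frozen=True)
class ResolutionSlice:
    resolution: int
    diagram: AUCDiagram2D
    alpha_b: float
    significant: np.ndarray


@dataclass(frozen=True)
class AUCDiagram3D:
    parameter: str
    prange: tuple
    alpha0: float
    slices: tuple                     # ResolutionSlice per resolution

    @property
    def resolutions(self) -> list[int]:
        return [s.resolution for s in self.slices]


@dataclass(frozen=True)
class BestCell:
    parameter: str
    lower: float
    upper: float
    auc: float

    @property
    def score(self) -> float:
        return abs(self.auc - 0.5)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class RefinementState:
    box: ParameterBox
    history: tuple
    stop_reason: str                  # no_change | degraded | max_iter


def _constraint_mask(events: pd.DataFrame, box: ParameterBox,
                     exclude: str | None = None) -> np.ndarray:
    mask = np.ones(len(events), dtype=bool)
    for param, (lo_name, hi_name) in PARAM_BOUNDS.items():
        if param == exclude:
            continue
        col = events[PARAM_COLUMN[param]].to_numpy()
        mask &= (col >= getattr(box, lo_name)) & (col <= getattr(box, hi_name))
    return mask


def _check_roster(roster: pd.DataFrame, groups):
    for g in groups:
        if (roster["group"] == g).sum() < 2:
            raise ValueError(f"need at least 2 subjects in group {g!r}")


def _rates(events: pd.DataFrame, roster: pd.DataFrame, parameter: str,
           lowers: np.ndarray, uppers: np.ndarray, constraints: ParameterBox,
           groups) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject rate tensors (n_subj, n_lower, n_upper) for each group."""
    col = PARAM_COLUMN[parameter]
    kept = events[_constraint_mask(events, constraints, exclude=parameter)]
    by_subject = {sid: np.sort(sub[col].to_numpy())
                  for sid, sub in kept.groupby("subject_id")}
    out = []
    for g in groups:
        sel = roster[roster["group"] == g]
        rates = np.empty((len(sel), lowers.size, uppers.size))
        for k, row in enumerate(sel.itertuples()):
            v = by_subject.get(row.subject_id, np.empty(0))
            lo_idx = np.searchsorted(v, lowers - _TOL, side="left")
            up_idx = np.searchsorted(v, uppers + _TOL, side="right")
            rates[k] = np.maximum(up_idx[None, :] - lo_idx[:, None], 0) \
                / row.valid_duration_s
        out.append(rates)
    return out[0], out[1]


def auc_diagram_2d(events: pd.DataFrame, roster: pd.DataFrame, parameter: str,
                   lower_bounds=None, upper_bounds=None,
                   constraints: ParameterBox | None = None,
                   min_width: float = 0.0, compute_p: bool = False,
                   groups=("patient", "control"),
                   grids: Mapping = DEFAULT_GRIDS) -> AUCDiagram2D:
    """2D AUC diagram of per-subject rates over a (lower, upper) bound grid.

    ``events`` is an event table (one row per accepted wave train),
    ``roster`` defines the subjects (columns subject_id, group,
    valid_duration_s) so that subjects without any event count with rate 0.
    Cells are defined where lower <= upper and upper - lower >= min_width.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    _check_roster(roster, groups)
    constraints = constraints or ParameterBox()
    lowers = np.asarray(grid_bounds(parameter, grids) if lower_bounds is None
                        else lower_bounds, dtype=float)
    uppers = lowers.copy() if upper_bounds is None else np.asarray(upper_bounds,
                                                                   dtype=float)
    pat, ctl = _rates(events, roster, parameter, lowers, uppers, constraints,
                      groups)
    valid = (uppers[None, :] - lowers[:, None]) >= (min_width - _TOL)
    flat = np.flatnonzero(valid)
    auc = np.full(valid.shape, np.nan)
    n1, n2 = pat.shape[0], ctl.shape[0]
    a = pat.reshape(n1, -1)[:, flat]
    b = ctl.reshape(n2, -1)[:, flat]
    auc.flat[flat] = auc_matrix(a, b)
    p = None
    if compute_p:
        p = np.full(valid.shape, np.nan)
        p.flat[flat] = mwu_p_matrix(a, b)
    return AUCDiagram2D(parameter=parameter, lower_bounds=lowers,
                        upper_bounds=uppers, auc=auc, n_patients=n1,
                        n_controls=n2, constraints=constraints,
                        min_width=min_width, p=p)


def auc_diagram_3d(events: pd.DataFrame, roster: pd.DataFrame, parameter: str,
                   prange: tuple = (1.0, 10.0),
                   resolutions: Sequence[int] = tuple(range(1, 24)),
                   constraints: ParameterBox | None = None,
                   alpha0: float = 0.05,
                   groups=("patient", "control")) -> AUCDiagram3D:
    """Stack of equal-bin 2D diagrams over resolutions with significance
    masking at the Sidak-corrected level alpha_B(R)."""
    lo, hi = prange
    if not hi > lo:
        raise ValueError("prange must be increasing")
    slices = []
    for r in resolutions:
        edges = np.linspace(lo, hi, r + 1)
        width = (hi - lo) / r
        d2 = auc_diagram_2d(events, roster, parameter,
                            lower_bounds=edges[:-1], upper_bounds=edges[1:],
                            constraints=constraints, min_width=width * (1 - 1e-9),
                            compute_p=True, groups=groups)
        n_cells = int(d2.defined.sum())
        assert n_cells == correction_count(r)
        alpha_b = bonferroni_alpha(alpha0, n_cells)
        signif = np.zeros(d2.auc.shape, dtype=bool)
        signif[d2.defined] = d2.p[d2.defined] <= alpha_b
        slices.append(ResolutionSlice(resolution=int(r), diagram=d2,
                                      alpha_b=alpha_b, significant=signif))
    return AUCDiagram3D(parameter=parameter, prange=(float(lo), float(hi)),
                        alpha0=alpha0, slices=tuple(slices))


def best_cell(d: AUCDiagram2D) -> BestCell:
    """Cell with the largest |AUC - 0.5|; ties broken toward the widest
    range, then the smallest lower bound."""
    defined = d.defined
    if not defined.any():
        raise ValueError("diagram has no defined cells")
    ii, jj = np.nonzero(defined)
    auc = d.auc[ii, jj]
    score = np.abs(auc - 0.5)
    width = d.upper_bounds[jj] - d.lower_bounds[ii]
    order = np.lexsort((d.lower_bounds[ii], -width, -score))
    k = order[0]
    return BestCell(parameter=d.parameter, lower=float(d.lower_bounds[ii[k]]),
                    upper=float(d.upper_bounds[jj[k]]), auc=float(auc[k]))


def _box_score(events: pd.DataFrame, roster: pd.DataFrame, box: ParameterBox,
               groups) -> float:
    """|AUC - 0.5| of the whole-box comparison under all four constraints."""
    kept = events[_constraint_mask(events, box)]
    counts = kept.groupby("subject_id").size()
    rates = {g: np.array([counts.get(r.subject_id, 0) / r.valid_duration_s
                          for r in roster[roster["group"] == g].itertuples()])
             for g in groups}
    from .stats import roc_auc
    return abs(roc_auc(rates[groups[0]], rates[groups[1]]) - 0.5)


def refine(events: pd.DataFrame, roster: pd.DataFrame,
           initial_box: ParameterBox | None = None,
           grids: Mapping = DEFAULT_GRIDS, eps: float = 0.01,
           delta: float = 0.05, max_iter: int = 10,
           groups=("patient", "control")) -> RefinementState:
    """Iterative restriction of the four-parameter box.

    Per iteration all four diagrams are rebuilt under the current box (each
    constrained by the *other* three parameters) and the best cell across
    diagrams is compared with the current whole-box score |AUC - 0.5|:
    improvement <= eps stops with ``no_change``; a drop > delta stops with
    ``degraded`` (the restriction is not applied); otherwise the cell's
    bounds replace that parameter's constraint.
    """
    _check_roster(roster, groups)
    box = initial_box or ParameterBox()
    score = _box_score(events, roster, box, groups)
    history = []
    stop = "max_iter"
    for it in range(1, max_iter + 1):
        candidates = [best_cell(auc_diagram_2d(events, roster, p,
                                               constraints=box, groups=groups,
                                               grids=grids))
                      for p in PARAMETERS]
        cand = max(candidates, key=lambda c: c.score)
        entry = {"iteration": it, "parameter": cand.parameter,
                 "lower": cand.lower, "upper": cand.upper, "auc": cand.auc,
                 "score": cand.score, "previous_score": score}
        if cand.score <= score + eps:
            entry["action"] = "stop"
            history.append(entry)
            stop = "no_change"
            break
        if cand.score < score - delta:
            entry["action"] = "revert"
            history.append(entry)
            stop = "degraded"
            break
        lo_name, hi_name = PARAM_BOUNDS[cand.parameter]
        box = replace(box, **{lo_name: cand.lower, hi_name: cand.upper})
        score = cand.score
        entry["action"] = "apply"
        history.append(entry)
    return RefinementState(box=box, history=tuple(history), stop_reason=stop)


# ---------------------------------------------------------------------------
# export / rendering

def diagram_to_frame(d, resolution: int | None = None,
                     alpha_b: float | None = None,
                     significant=None) -> pd.DataFrame:
    """Long-format table of a 2D diagram (or of every slice of a 3D one)."""
    if isinstance(d, AUCDiagram3D):
        return pd.concat([diagram_to_frame(s.diagram, s.resolution, s.alpha_b,
                                           s.significant) for s in d.slices],
                         ignore_index=True)
    ii, jj = np.nonzero(d.defined)
    frame = pd.DataFrame({
        "parameter": d.parameter,
        "lower": d.lower_bounds[ii],
        "upper": d.upper_bounds[jj],
        "resolution": resolution if resolution is not None else len(d.lower_bounds),
        "auc": d.auc[ii, jj],
        "p": d.p[ii, jj] if d.p is not None else np.nan,
        "alpha_b": alpha_b if alpha_b is not None else np.nan,
        "significant": (significant[ii, jj] if significant is not None
                        else pd.array([pd.NA] * ii.size, dtype="boolean")),
    })
    return frame


def refinement_to_json(state: RefinementState, path) -> None:
    with open(path, "w") as fh:
        for entry in state.history:
            fh.write(json.dumps(entry) + "\n")


def render_diagram(d: AUCDiagram2D, path, masked=None) -> None:
    """Heatmap render: lower bound on the abscissa, upper bound on the
    ordinate, jet colormap over AUC in [0, 1]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    auc = d.auc.copy()
    if masked is not None:
        auc[~masked] = np.nan
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(d.lower_bounds, d.upper_bounds, auc.T, cmap="jet",
                         vmin=0.0, vmax=1.0, shading="nearest")
    ax.set_xlabel(f"{d.parameter} lower bound")
    ax.set_ylabel(f"{d.parameter} upper bound")
    fig.colorbar(mesh, ax=ax, label="AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_diagram_3d(d3: AUCDiagram3D, path) -> None:
    """Per-resolution significance-masked slice panels of a 3D diagram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(d3.slices)
    ncol = min(n, 4)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for k, s in enumerate(d3.slices):
        ax = axes.flat[k]
        ax.set_axis_on()
        auc = s.diagram.auc.copy()
        auc[~s.significant] = np.nan
        ax.pcolormesh(s.diagram.lower_bounds, s.diagram.upper_bounds, auc.T,
                      cmap="jet", vmin=0.0, vmax=1.0, shading="nearest")
        ax.set_title(f"R={s.resolution}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
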