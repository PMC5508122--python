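"""The dual-panel diamond plot and the rule-based relevance classifier.

Each questionnaire item occupies one row.  The left panel shows the item's
raw scores (jittered) and its mean as a diamond spanning the mean's
confidence interval on the response-scale axis; the diamond fill encodes
the mean on a red (low) -> blue (scale midpoint) -> green (high) gradient.
The right panel shows, per target, a diamond spanning the correlation's
confidence interval on the [-1, 1] axis, filled on a red (strong negative)
-> gray (zero) -> green (strong positive) gradient and stroked in a fixed
per-target color.  A banner reports each target's R^2 interval.

The figure description is assembled as a renderer-independent
:class:`PlotSpec` (JSON-serializable, used for golden-file tests) and only
then drawn with matplotlib.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import ItemMetadata, QuestionnaireDataset, infer_scale_bounds
from .estimation import (
    DEFAULT_ASSOC_LEVEL,
    DEFAULT_MEAN_LEVEL,
    DEFAULT_RSQ_LEVEL,
    AssociationEstimate,
    EstimateWithCI,
    EstimationResults,
    estimate_all,
)

Color = tuple[float, float, float]

RED: Color = (1.0, 0.0, 0.0)
GREEN: Color = (0.0, 1.0, 0.0)
BLUE: Color = (0.0, 0.0, 1.0)
GRAY: Color = (0.5, 0.5, 0.5)

#: Stroke colors cycled over targets; first two match the canonical figure
#: convention (red stroke = first target, blue stroke = second).
TARGET_STROKE_PALETTE: tuple[Color, ...] = (
    (0.8, 0.0, 0.0),
    (0.0, 0.0, 0.8),
    (0.0, 0.6, 0.0),
    (0.7, 0.5, 0.0),
    (0.5, 0.0, 0.7),
)

DIAMOND_HALF_HEIGHT = 0.25  # in row units
DEFAULT_JITTER_SEED = 42
DEFAULT_H_SPREAD = 0.45  # scale units
DEFAULT_V_SPREAD = 0.2  # row units


class PlotError(ValueError):
    """Raised for invalid plot specifications or render requests."""


# ---------------------------------------------------------------------------
# color maps


@dataclass(frozen=True)
class ColorMap:
    """Three-anchor piecewise-linear color gradient.

    Interpolation is linear per RGB channel within each half of the domain,
    which keeps every channel piecewise monotone and the anchor colors
    exactly attained at min, mid, and max.
    """

    low_color: Color
    mid_color: Color
    high_color: Color
    domain_min: float
    domain_mid: float
    domain_max: float

    def __post_init__(self) -> None:
        if not self.domain_min < self.domain_mid < self.domain_max:
            raise PlotError("color map domain must satisfy min < mid < max")

    def __call__(self, value: float) -> Color:
        if not self.domain_min <= value <= self.domain_max:
            raise PlotError(
                f"value {value} outside color map domain "
                f"[{self.domain_min}, {self.domain_max}]"
            )
        if value <= self.domain_mid:
            t = (value - self.domain_min) / (self.domain_mid - self.domain_min)
            a, b = self.low_color, self.mid_color
        else:
            t = (value - self.domain_mid) / (self.domain_max - self.domain_mid)
            a, b = self.mid_color, self.high_color
        return tuple(float((1 - t) * ca + t * cb) for ca, cb in zip(a, b))  # type: ignore[return-value]


def mean_color(mean: float, scale_min: float, scale_max: float) -> Color:
    """Fill color for an item mean: red (low) -> blue (midpoint) -> green (high)."""
    cmap = ColorMap(RED, BLUE, GREEN, scale_min, (scale_min + scale_max) / 2.0, scale_max)
    return cmap(mean)


def assoc_color(r: float) -> Color:
    """Fill color for a correlation: red (-1) -> gray (0) -> green (+1)."""
    cmap = ColorMap(RED, GRAY, GREEN, -1.0, 0.0, 1.0)
    return cmap(r)


# ---------------------------------------------------------------------------
# jitter, ordering


def jitter_points(
    scores: Sequence[float],
    seed: int = DEFAULT_JITTER_SEED,
    h_spread: float = DEFAULT_H_SPREAD,
    v_spread: float = DEFAULT_V_SPREAD,
) -> np.ndarray:
    """Jittered (x, y) positions for the non-missing raw scores of one item.

    x is the score plus a uniform offset in +/- h_spread; y is a uniform
    offset in +/- v_spread around the row center.  Deterministic given seed.
    """
    if h_spread < 0 or v_spread < 0:
        raise PlotError("jitter spreads must be non-negative")
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    rng = np.random.default_rng(seed)
    n = scores.size
    dx = rng.uniform(-h_spread, h_spread, size=n) if h_spread else np.zeros(n)
    dy = rng.uniform(-v_spread, v_spread, size=n) if v_spread else np.zeros(n)
    return np.column_stack([scores + dx, dy])


def order_items(
    results: EstimationResults,
    mode: str = "by-mean-descending",
    target_id: str | None = None,
) -> list[str]:
    """Permutation of the determinant ids in display order.

    Modes: ``by-mean-descending`` / ``by-mean-ascending`` (sort by mean
    point estimate), ``by-association`` (sort descending by the point
    correlation with ``target_id``).  Sorting is stable, so ties keep the
    original input order; items without a usable estimate sort last.
    """
    ids = list(results.determinant_ids)

    if mode in ("by-mean-descending", "by-mean-ascending"):
        def key(item: str) -> float:
            est = results.means.get(item)
            return est.point if est is not None else -np.inf
        reverse = mode == "by-mean-descending"
    elif mode == "by-association":
        if target_id is None or target_id not in results.target_ids:
            raise PlotError(f"by-association ordering needs a known target id, got {target_id!r}")
        def key(item: str) -> float:
            a = results.association(item, target_id)
            return a.estimate.point if a is not None else -np.inf
        reverse = True
    else:
        raise PlotError(f"unknown ordering mode {mode!r}")

    # Stable sort on the key only; reverse via negation to preserve tie order.
    return sorted(ids, key=lambda i: -key(i) if reverse else key(i))


# ---------------------------------------------------------------------------
# relevance classification


@dataclass(frozen=True)
class RelevanceThresholds:
    """Cut-offs for the rule-based relevance patterns.

    ``weak_r`` / ``strong_r`` bound the ambiguous band of association
    magnitudes; ``extreme_fraction`` is how close (as a fraction of the
    scale range) a mean must sit to a scale end to count as "near the
    extreme".  ``target_high_undesirable`` states the coding of the targets:
    True means higher target scores indicate more inclination toward the
    behavior the intervention discourages.
    """

    weak_r: float = 0.1
    strong_r: float = 0.3
    extreme_fraction: float = 0.15
    target_high_undesirable: bool = True


@dataclass(frozen=True)
class RelevanceClassification:
    label: str  # already-favorable | unassociated | relevant-negate | relevant-reinforce
    action: str  # confirm | deprioritize | negate | reinforce
    low_confidence: bool
    driving_target: str
    max_abs_r: float


def classify_relevance(
    mean_est: EstimateWithCI,
    scale_min: float,
    scale_max: float,
    assoc_ests: Sequence[AssociationEstimate],
    thresholds: RelevanceThresholds = RelevanceThresholds(),
) -> RelevanceClassification:
    """Classify one item into an intervention-relevance pattern.

    The association with the largest |r| drives the decision:

    * |r| below ``weak_r``: the item is unassociated with every target and
      is deprioritized, whatever its mean.
    * otherwise, the sign of r orients the scale: the end of the item scale
      that pulls the target in the undesirable direction is located, and
      - a mean already near the opposite (favorable) extreme means the
        population holds the belief in the safe direction: confirm it;
      - a positive association with a non-extreme mean marks a belief to
        negate;
      - a negative association with a non-extreme mean marks a belief to
        reinforce.

    Associations in the ambiguous band [weak_r, strong_r) yield the same
    labels flagged low-confidence.
    """
    if not assoc_ests:
        raise PlotError("classify_relevance needs at least one association estimate")
    if not scale_min < scale_max:
        raise PlotError("scale_min must be below scale_max")
    driver = max(assoc_ests, key=lambda a: abs(a.estimate.point))
    r = driver.estimate.point
    if not thresholds.target_high_undesirable:
        r = -r
    abs_r = abs(r)
    frac = (mean_est.point - scale_min) / (scale_max - scale_min)

    if abs_r < thresholds.weak_r:
        return RelevanceClassification(
            "unassociated", "deprioritize", False, driver.target_id, abs(driver.estimate.point)
        )
    low_conf = abs_r < thresholds.strong_r
    near_favorable = (
        frac <= thresholds.extreme_fraction if r > 0 else frac >= 1 - thresholds.extreme_fraction
    )
    if near_favorable:
        label, action = "already-favorable", "confirm"
    elif r > 0:
        label, action = "relevant-negate", "negate"
    else:
        label, action = "relevant-reinforce", "reinforce"
    return RelevanceClassification(
        label, action, low_conf, driver.target_id, abs(driver.estimate.point)
    )


# ---------------------------------------------------------------------------
# plot specification


def estimate_count(n_items: int, n_targets: int) -> int:
    """Number of point/bound estimates a reader must evaluate jointly.

    Each item contributes its mean plus interval bounds (3 numbers) and,
    per target, a correlation plus bounds (3 more): n_items * 3 * (1 + n_targets).
    """
    if n_items < 0 or n_targets < 0:
        raise PlotError("counts must be non-negative")
    return n_items * 3 * (1 + n_targets)


@dataclass(frozen=True)
class DiamondGlyph:
    """One confidence-interval diamond: widest at the point estimate."""

    row_index: int
    left_x: float
    center_x: float
    right_x: float
    fill_color: Color
    stroke_color: Color

    def __post_init__(self) -> None:
        if not self.left_x <= self.center_x <= self.right_x:
            raise PlotError("diamond requires left_x <= center_x <= right_x")


@dataclass
class PlotRow:
    item_id: str
    question_text: str
    left_anchor: str
    right_anchor: str
    available: bool = True
    failure_reason: str = ""


@dataclass
class PlotSpec:
    """Renderer-independent description of the full two-panel figure."""

    rows: list[PlotRow]
    left_diamonds: list[DiamondGlyph]
    left_points: list[np.ndarray]  # per row, (k, 2) jittered raw-score positions
    right_diamonds: list[list[DiamondGlyph]]  # per row, one glyph per target
    banner: list[tuple[str, EstimateWithCI, Color]]  # (target_id, R^2 estimate, stroke)
    target_ids: list[str]
    scale_min: float
    scale_max: float
    assoc_min: float = -1.0
    assoc_max: float = 1.0

    def validate(self) -> None:
        n_avail = sum(r.available for r in self.rows)
        if len(self.left_diamonds) != n_avail:
            raise PlotError("one left-panel diamond required per available row")
        n_right = sum(len(g) for g in self.right_diamonds)
        if n_right != n_avail * len(self.target_ids):
            raise PlotError("right-panel diamond count must be rows x targets")

    def displayed_estimate_count(self) -> int:
        """Total point/bound estimates shown (3 per diamond)."""
        return 3 * (len(self.left_diamonds) + sum(len(g) for g in self.right_diamonds))

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "left_diamonds": [vars(d) for d in self.left_diamonds],
            "left_points": [p.tolist() for p in self.left_points],
            "right_diamonds": [[vars(d) for d in row] for row in self.right_diamonds],
            "banner": [
                {
                    "target_id": t,
                    "point": e.point,
                    "lower": e.lower,
                    "upper": e.upper,
                    "level": e.confidence_level,
                    "stroke": list(stroke),
                }
                for t, e, stroke in self.banner
            ],
            "target_ids": self.target_ids,
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
            "assoc_min": self.assoc_min,
            "assoc_max": self.assoc_max,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class PlotOptions:
    order_mode: str = "by-mean-descending"
    order_target: str | None = None
    conf_means: float = DEFAULT_MEAN_LEVEL
    conf_assoc: float = DEFAULT_ASSOC_LEVEL
    conf_rsq: float = DEFAULT_RSQ_LEVEL
    jitter_seed: int = DEFAULT_JITTER_SEED
    h_spread: float = DEFAULT_H_SPREAD
    v_spread: float = DEFAULT_V_SPREAD


def build_ciber_plot(
    dataset: QuestionnaireDataset,
    determinant_ids: Sequence[str],
    target_ids: Sequence[str] = (),
    metadata: Sequence[ItemMetadata] | None = None,
    options: PlotOptions | None = None,
    results: EstimationResults | None = None,
) -> PlotSpec:
    """Assemble the full two-panel relevance figure as a :class:`PlotSpec`.

    Estimates are computed via :func:`ciber.estimation.estimate_all` unless
    precomputed ``results`` are supplied.  Items whose estimation failed are
    kept as labeled empty rows rather than dropped, so a selection decision
    is never biased by silent omission.
    """
    options = options or PlotOptions()
    meta_by_id = {m.item_id: m for m in metadata or []}
    if results is None:
        results = estimate_all(
            dataset,
            determinant_ids,
            target_ids,
            conf_means=options.conf_means,
            conf_assoc=options.conf_assoc,
            conf_rsq=options.conf_rsq,
        )
    if not results.means:
        raise PlotError("no item could be estimated; nothing to plot")

    ordered = order_items(results, options.order_mode, options.order_target)

    # One shared response-scale axis: the union of the per-item bounds.
    bounds = [
        infer_scale_bounds(dataset, item, meta_by_id.get(item))
        for item in ordered
        if item in results.means
    ]
    scale_min = min(b[0] for b in bounds)
    scale_max = max(b[1] for b in bounds)

    rows: list[PlotRow] = []
    left_diamonds: list[DiamondGlyph] = []
    left_points: list[np.ndarray] = []
    right_diamonds: list[list[DiamondGlyph]] = []
    strokes = {
        t: TARGET_STROKE_PALETTE[i % len(TARGET_STROKE_PALETTE)]
        for i, t in enumerate(results.target_ids)
    }

    for row_index, item in enumerate(ordered):
        meta = meta_by_id.get(item)
        row = PlotRow(
            item_id=item,
            question_text=meta.question_text if meta else item,
            left_anchor=meta.left_anchor if meta else "",
            right_anchor=meta.right_anchor if meta else "",
        )
        est = results.means.get(item)
        if est is None:
            row.available = False
            row.failure_reason = results.failures.get(item, "estimation failed")
            rows.append(row)
            left_points.append(np.empty((0, 2)))
            right_diamonds.append([])
            continue
        row_glyphs = []
        for t in results.target_ids:
            a = results.association(item, t)
            if a is None:
                continue
            e = a.estimate
            row_glyphs.append(
                DiamondGlyph(row_index, e.lower, e.point, e.upper, assoc_color(e.point), strokes[t])
            )
        if len(row_glyphs) < len(results.target_ids):
            # A missing association would leave the row uninterpretable for
            # selection; keep it as a labeled empty row.
            row.available = False
            row.failure_reason = results.failures.get(item, "association unavailable")
            rows.append(row)
            left_points.append(np.empty((0, 2)))
            right_diamonds.append([])
            continue
        rows.append(row)
        fill = mean_color(min(max(est.point, scale_min), scale_max), scale_min, scale_max)
        left_diamonds.append(
            DiamondGlyph(row_index, est.lower, est.point, est.upper, fill, (0.2, 0.2, 0.2))
        )
        # Per-row jitter seed offset keeps rows visually independent but
        # the whole figure deterministic.
        left_points.append(
            jitter_points(
                dataset.numeric_column(item),
                seed=options.jitter_seed + row_index,
                h_spread=options.h_spread,
                v_spread=options.v_spread,
            )
        )
        right_diamonds.append(row_glyphs)

    banner = [
        (t, results.rsq[t].estimate, strokes[t]) for t in results.target_ids if t in results.rsq
    ]
    spec = PlotSpec(
        rows=rows,
        left_diamonds=left_diamonds,
        left_points=left_points,
        right_diamonds=right_diamonds,
        banner=banner,
        target_ids=list(results.target_ids),
        scale_min=scale_min,
        scale_max=scale_max,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# rendering

SUPPORTED_FORMATS = ("svg", "png", "pdf")


def _diamond_vertices(d: DiamondGlyph, y: float, half_height: float) -> list[tuple[float, float]]:
    return [
        (d.left_x, y),
        (d.center_x, y + half_height),
        (d.right_x, y),
        (d.center_x, y - half_height),
    ]


def render(
    spec: PlotSpec,
    path: str | Path,
    fmt: str | None = None,
    width: float = 11.0,
    height: float | None = None,
) -> Path:
    """Draw a :class:`PlotSpec` with matplotlib and write it to ``path``.

    SVG output is byte-stable: rendering the same spec twice with the same
    settings produces identical files (fixed hash salt, no timestamp).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon

    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".") or "svg").lower()
    if fmt not in SUPPORTED_FORMATS:
        raise PlotError(f"unsupported format {fmt!r}; choose one of {SUPPORTED_FORMATS}")
    spec.validate()

    n_rows = len(spec.rows)
    height = height or max(3.0, 0.42 * n_rows + 1.6)
    with matplotlib.rc_context({"svg.hashsalt": "ciber"}):
        fig, (ax_l, ax_r) = plt.subplots(
            1,
            2,
            figsize=(width, height),
            sharey=True,
            gridspec_kw={"width_ratios": [3, 2], "wspace": 0.08},
        )
        pad = 0.04 * (spec.scale_max - spec.scale_min)
        ax_l.set_xlim(spec.scale_min - 0.5 - pad, spec.scale_max + 0.5 + pad)
        ax_r.set_xlim(spec.assoc_min - 0.05, spec.assoc_max + 0.05)
        ax_l.set_ylim(-0.6, n_rows - 0.4)
        ax_l.invert_yaxis()  # first row on top

        for row_index, row in enumerate(spec.rows):
            y = row_index
            if not row.available:
                ax_l.text(
                    (spec.scale_min + spec.scale_max) / 2,
                    y,
                    f"[unavailable: {row.failure_reason}]",
                    ha="center",
                    va="center",
                    fontsize=7,
                    color="0.4",
                    style="italic",
                )
            pts = spec.left_points[row_index]
            if pts.size:
                ax_l.scatter(
                    pts[:, 0], pts[:, 0] * 0 + y + pts[:, 1], s=4, color="0.55", alpha=0.35,
                    linewidths=0, zorder=1,
                )
            if row.left_anchor:
                ax_l.text(
                    spec.scale_min - 0.45 - pad, y, row.left_anchor,
                    ha="left", va="center", fontsize=6, color="0.3",
                )
            if row.right_anchor:
                ax_l.text(
                    spec.scale_max + 0.45 + pad, y, row.right_anchor,
                    ha="right", va="center", fontsize=6, color="0.3",
                )

        for d in spec.left_diamonds:
            ax_l.add_patch(
                Polygon(
                    _diamond_vertices(d, d.row_index, DIAMOND_HALF_HEIGHT),
                    closed=True,
                    facecolor=d.fill_color,
                    edgecolor=d.stroke_color,
                    linewidth=0.8,
                    zorder=3,
                )
            )

        n_targets = max(1, len(spec.target_ids))
        offsets = np.linspace(-0.18, 0.18, n_targets) if n_targets > 1 else [0.0]
        ax_r.axvline(0.0, color="0.8", linewidth=0.8, zorder=0)
        for row_glyphs in spec.right_diamonds:
            for j, d in enumerate(row_glyphs):
                ax_r.add_patch(
                    Polygon(
                        _diamond_vertices(d, d.row_index + offsets[j], DIAMOND_HALF_HEIGHT * 0.8),
                        closed=True,
                        facecolor=d.fill_color,
                        edgecolor=d.stroke_color,
                        linewidth=1.0,
                        zorder=3,
                    )
                )

        ax_l.set_yticks(range(n_rows))
        ax_l.set_yticklabels([r.question_text for r in spec.rows], fontsize=7)
        ax_l.set_xlabel("response scale")
        ax_r.set_xlabel("correlation")
        ax_l.tick_params(axis="y", length=0)

        banner_parts = [
            f"$R^2$[{t}] = {e.point:.2f} [{e.lower:.2f}; {e.upper:.2f}]"
            for t, e, _ in spec.banner
        ]
        if banner_parts:
            fig.suptitle("   ".join(banner_parts), fontsize=9)
        fig.subplots_adjust(left=0.32, right=0.98, top=0.93, bottom=0.08)
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
    return path
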