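"""Edatopic grids: ecosite regions in (SNR, SMR) space and point classification.

An edatopic grid charts ecosites on two axes — soil nutrient regime (SNR,
horizontal, class units in [0, 5]) and soil moisture regime (SMR, vertical,
[0, 7]).  The original field classification draws each ecosite as an
ellipse; ellipses overlap because neighbouring ecosites are told apart by
vegetation and soil type, information a regime-only map does not have.
For mapping, overlapping ecosites are first *combined* under explicit
rules and the combined ellipses are then *transformed* into a system of
non-overlapping axis-aligned rectangles chosen to keep as many field plots
as possible inside their own ecosite while intruding as little as possible
on the neighbours.  Points are classified by rectangle membership, with a
nearest-rectangle fallback so classification is total over the domain.

Rectangle intervals are half-open ``[lo, hi)`` on both axes; the upper
domain edge is inclusive so the domain is covered exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GridError",
    "EcositeEllipse",
    "EcositeRectangle",
    "EdatopicGrid",
    "combine_ecosites",
    "ellipse_assign",
    "transform_to_rectangles",
    "classify_point",
    "grid_centers",
    "load_grid",
    "load_default_grid",
    "DEFAULT_REGIONS",
]

DEFAULT_REGIONS = ("acadian", "maritime_boreal")
_GRID_FILES = {
    "acadian": "grid_acadian.yaml",
    "maritime_boreal": "grid_maritime_boreal.yaml",
}


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class EcositeEllipse:
    """Axis-aligned ecosite ellipse from the original (field) edatopic grid."""

    ecosite_id: int
    center: tuple[float, float]  # (snr, smr)
    semi_axes: tuple[float, float]  # (snr half-width, smr half-height)

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise GridError(f"ellipse {self.ecosite_id}: semi-axes must be > 0")

    def normalized_distance(self, snr: float, smr: float) -> float:
        """sqrt(((snr-cx)/a)^2 + ((smr-cy)/b)^2); <= 1 means containment."""
        cx, cy = self.center
        a, b = self.semi_axes
        return math.hypot((snr - cx) / a, (smr - cy) / b)

    def contains(self, snr: float, smr: float) -> bool:
        return self.normalized_distance(snr, smr) <= 1.0

    def bounding_box(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center
        a, b = self.semi_axes
        return (cx - a, cx + a), (cy - b, cy + b)


@dataclass(frozen=True)
class EcositeRectangle:
    """Axis-aligned ecosite rectangle of the simplified edatopic grid."""

    ecosite_id: int
    snr_interval: tuple[float, float]  # [lo, hi)
    smr_interval: tuple[float, float]  # [lo, hi)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("snr", self.snr_interval),
            ("smr", self.smr_interval),
        ):
            if not lo < hi:
                raise GridError(
                    f"rectangle {self.ecosite_id}: {name} interval [{lo}, {hi}) is empty"
                )

    def contains(self, snr: float, smr: float, domain=None) -> bool:
        """Half-open membership; the upper edge is inclusive where it
        coincides with the domain boundary (``domain`` = ((snr_lo, snr_hi),
        (smr_lo, smr_hi)))."""
        (xlo, xhi), (ylo, yhi) = self.snr_interval, self.smr_interval
        x_hi_inc = domain is not None and xhi >= domain[0][1]
        y_hi_inc = domain is not None and yhi >= domain[1][1]
        in_x = xlo <= snr < xhi or (x_hi_inc and snr == xhi)
        in_y = ylo <= smr < yhi or (y_hi_inc and smr == yhi)
        return in_x and in_y

    def distance(self, snr: float, smr: float) -> float:
        """Euclidean distance from a point to the (closed) rectangle."""
        (xlo, xhi), (ylo, yhi) = self.snr_interval, self.smr_interval
        dx = max(xlo - snr, 0.0, snr - xhi)
        dy = max(ylo - smr, 0.0, smr - yhi)
        return math.hypot(dx, dy)

    def area(self) -> float:
        (xlo, xhi), (ylo, yhi) = self.snr_interval, self.smr_interval
        return (xhi - xlo) * (yhi - ylo)

    def overlaps(self, other: "EcositeRectangle") -> bool:
        (axl, axh), (ayl, ayh) = self.snr_interval, self.smr_interval
        (bxl, bxh), (byl, byh) = other.snr_interval, other.smr_interval
        return axl < bxh and bxl < axh and ayl < byh and byl < ayh


@dataclass(frozen=True)
class EdatopicGrid:
    """Per-ecoregion ecosite grid: rectangles, original ellipses and rules."""

    region: str
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 5.0), (0.0, 7.0))
    rectangles: tuple[EcositeRectangle, ...] = ()
    ellipses: tuple[EcositeEllipse, ...] = ()
    combination_rules: dict[int, tuple[int, int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rectangles:
            raise GridError(f"grid {self.region!r}: needs at least one rectangle")
        ids = [r.ecosite_id for r in self.rectangles]
        if len(set(ids)) != len(ids):
            raise GridError(f"grid {self.region!r}: duplicate rectangle ecosite ids")
        for r1, r2 in itertools.combinations(self.rectangles, 2):
            if r1.overlaps(r2):
                raise GridError(
                    f"grid {self.region!r}: rectangles {r1.ecosite_id} and "
                    f"{r2.ecosite_id} overlap"
                )
        (xlo, xhi), (ylo, yhi) = self.domain
        for e in self.ellipses:
            cx, cy = e.center
            if not (xlo <= cx <= xhi and ylo <= cy <= yhi):
                raise GridError(
                    f"grid {self.region!r}: ellipse {e.ecosite_id} center outside domain"
                )

    @property
    def ecosite_ids(self) -> tuple[int, ...]:
        return tuple(r.ecosite_id for r in self.rectangles)

    def rectangle(self, ecosite_id: int) -> EcositeRectangle:
        for r in self.rectangles:
            if r.ecosite_id == ecosite_id:
                return r
        raise GridError(f"grid {self.region!r}: no rectangle for ecosite {ecosite_id}")

    def clamp(self, snr: float, smr: float) -> tuple[float, float]:
        (xlo, xhi), (ylo, yhi) = self.domain
        return (min(max(snr, xlo), xhi), min(max(smr, ylo), yhi))

    def classify(self, snr: float, smr: float) -> tuple[int, bool]:
        return classify_point(self, snr, smr)


# -- combining ecosites --------------------------------------------------


def combine_ecosites(
    original_ids,
    rules: dict[int, tuple[int, int | None]],
) -> tuple[tuple[int, ...], dict[int, int]]:
    """Apply combination rules mapping original to combined ecosite ids.

    ``rules`` maps ``original_id -> (combined_id, condition)`` where the
    condition tag records *why* two ecosites may be merged (1: separated
    only by soil and vegetation type; 2: by soil type alone; 3: by
    vegetation type alone — never by field-assessed SMR/SNR).  Returns the
    distinct combined ids (sorted) and the original->combined map.
    """
    relabel: dict[int, int] = {}
    for oid in original_ids:
        oid = int(oid)
        if oid not in rules:
            raise GridError(f"no combination rule for original ecosite {oid}")
        combined, condition = rules[oid]
        if condition is not None and condition not in (1, 2, 3):
            raise GridError(
                f"original ecosite {oid}: condition tag must be 1, 2 or 3"
            )
        relabel[oid] = int(combined)
    combined_ids = tuple(sorted(set(relabel.values())))
    return combined_ids, relabel


# -- ellipse assignment --------------------------------------------------


def ellipse_assign(ellipses, snr: float, smr: float) -> int | None:
    """Assign a point to the containing ellipse with the nearest
    (normalized) center; ``None`` when no ellipse contains the point."""
    ellipses = list(ellipses)
    if not ellipses:
        raise GridError("ellipse_assign needs a non-empty ellipse list")
    if math.isnan(snr) or math.isnan(smr):
        raise GridError("ellipse_assign: NaN coordinates")
    best_id, best_d = None, np.inf
    for e in ellipses:
        d = e.normalized_distance(snr, smr)
        if d <= 1.0 and (d < best_d or (d == best_d and best_id is not None
                                        and e.ecosite_id < best_id)):
            best_id, best_d = e.ecosite_id, d
    return best_id


# -- ellipse -> rectangle transformation --------------------------------


def _snap_outward(lo: float, hi: float, cuts: np.ndarray) -> tuple[float, float]:
    """Round [lo, hi] outward to lattice cuts, guaranteeing a non-empty
    interval (needs >= 2 distinct cuts)."""
    below, above = cuts[cuts <= lo], cuts[cuts >= hi]
    lo_s = float(below.max()) if below.size else float(cuts.min())
    hi_s = float(above.min()) if above.size else float(cuts.max())
    if hi_s <= lo_s:
        higher = cuts[cuts > lo_s]
        if higher.size:
            hi_s = float(higher.min())
        else:
            hi_s = lo_s
            lo_s = float(cuts[cuts < hi_s].max())
    return lo_s, hi_s


def _count_inside(rect: EcositeRectangle, pts: np.ndarray, domain) -> int:
    if len(pts) == 0:
        return 0
    return int(
        sum(rect.contains(x, y, domain=domain) for x, y in pts)
    )


def _best_rectangle(
    own: np.ndarray,
    other: np.ndarray,
    snr_cuts: np.ndarray,
    smr_cuts: np.ndarray,
    fixed: list[EcositeRectangle],
    lam: float,
    domain,
    ecosite_id: int,
) -> tuple[EcositeRectangle | None, float]:
    """Exhaustive search over the cut lattice for the rectangle maximizing
    own-plot capture minus ``lam`` times foreign-plot capture, disjoint from
    the already-fixed rectangles.  Ties break toward smaller area, then
    lexicographically smaller bounds, so the result is deterministic."""
    best, best_key = None, None
    for i, j in itertools.combinations(range(len(snr_cuts)), 2):
        for k, l in itertools.combinations(range(len(smr_cuts)), 2):
            rect = EcositeRectangle(
                ecosite_id,
                (float(snr_cuts[i]), float(snr_cuts[j])),
                (float(smr_cuts[k]), float(smr_cuts[l])),
            )
            if any(rect.overlaps(f) for f in fixed):
                continue
            score = _count_inside(rect, own, domain) - lam * _count_inside(
                rect, other, domain
            )
            key = (
                -score,
                rect.area(),
                rect.snr_interval,
                rect.smr_interval,
            )
            if best_key is None or key < best_key:
                best, best_key = rect, key
    return best, (-best_key[0] if best_key is not None else -np.inf)


def _expand_to_partition(
    rects: list[EcositeRectangle],
    domain,
    cuts: tuple[np.ndarray, np.ndarray],
) -> list[EcositeRectangle]:
    """Grow rectangle faces one lattice step at a time (round robin) until
    no rectangle can grow, annexing the uncovered domain."""
    snr_cuts, smr_cuts = cuts
    rects = list(rects)
    (dxlo, dxhi), (dylo, dyhi) = domain

    def step(vals: np.ndarray, v: float, up: bool) -> float | None:
        cand = vals[vals > v] if up else vals[vals < v]
        if len(cand) == 0:
            return None
        return float(cand.min() if up else cand.max())

    grew = True
    while grew:
        grew = False
        for idx, rect in enumerate(rects):
            others = rects[:idx] + rects[idx + 1 :]
            (xlo, xhi), (ylo, yhi) = rect.snr_interval, rect.smr_interval
            for direction in ("left", "right", "down", "up"):
                if direction == "left":
                    nv = step(snr_cuts, xlo, up=False)
                    if nv is None or nv < dxlo:
                        continue
                    trial = EcositeRectangle(rect.ecosite_id, (nv, xhi), (ylo, yhi))
                elif direction == "right":
                    nv = step(snr_cuts, xhi, up=True)
                    if nv is None or nv > dxhi:
                        continue
                    trial = EcositeRectangle(rect.ecosite_id, (xlo, nv), (ylo, yhi))
                elif direction == "down":
                    nv = step(smr_cuts, ylo, up=False)
                    if nv is None or nv < dylo:
                        continue
                    trial = EcositeRectangle(rect.ecosite_id, (xlo, xhi), (nv, yhi))
                else:
                    nv = step(smr_cuts, yhi, up=True)
                    if nv is None or nv > dyhi:
                        continue
                    trial = EcositeRectangle(rect.ecosite_id, (xlo, xhi), (ylo, nv))
                if any(trial.overlaps(o) for o in others):
                    continue
                rects[idx] = trial
                (xlo, xhi), (ylo, yhi) = trial.snr_interval, trial.smr_interval
                grew = True
    return rects


def transform_to_rectangles(
    ellipses,
    plots,
    boundary_lattice: float | tuple = 0.25,
    lam: float = 1.0,
    domain=((0.0, 5.0), (0.0, 7.0)),
    expand: bool = True,
) -> list[EcositeRectangle]:
    """Transform (combined) ecosite ellipses into disjoint rectangles.

    Greedy construction: ecosites are processed in descending plot count;
    for each, the axis-aligned rectangle over the cut lattice maximizing
    ``own plots inside - lam * other plots inside`` is chosen, subject to
    disjointness from already-fixed rectangles.  An ecosite with no plots
    is seeded from its ellipse's bounding box (snapped outward to the
    lattice, clipped against fixed rectangles).  When ``expand`` is true, a
    final face-growing pass annexes the uncovered domain so the rectangles
    partition it.

    Parameters
    ----------
    ellipses:
        One :class:`EcositeEllipse` per *combined* ecosite id.
    plots:
        Iterable of ``(snr, smr, ecosite_id)`` with combined ids.
    boundary_lattice:
        Either a lattice spacing in class units (cuts at every multiple
        within the domain) or an explicit ``(snr_cuts, smr_cuts)`` pair.
    """
    ellipses = list(ellipses)
    if not ellipses:
        raise GridError("transform_to_rectangles needs at least one ellipse")
    by_id = {e.ecosite_id: e for e in ellipses}
    plots = [(float(x), float(y), int(c)) for x, y, c in plots]
    unknown = {c for _, _, c in plots} - set(by_id)
    if unknown:
        raise GridError(f"plots reference unknown ecosite ids {sorted(unknown)}")

    (dxlo, dxhi), (dylo, dyhi) = domain
    if isinstance(boundary_lattice, (int, float)):
        spacing = float(boundary_lattice)
        snr_cuts = np.round(np.arange(dxlo, dxhi + spacing / 2, spacing), 10)
        smr_cuts = np.round(np.arange(dylo, dyhi + spacing / 2, spacing), 10)
    else:
        snr_cuts = np.asarray(boundary_lattice[0], dtype=float)
        smr_cuts = np.asarray(boundary_lattice[1], dtype=float)

    pts = {
        eid: np.array([(x, y) for x, y, c in plots if c == eid], dtype=float).reshape(
            -1, 2
        )
        for eid in by_id
    }
    # descending plot count; ties by ecosite id for determinism
    order = sorted(by_id, key=lambda eid: (-len(pts[eid]), eid))

    fixed: list[EcositeRectangle] = []
    for eid in order:
        own = pts[eid]
        other = np.array(
            [(x, y) for x, y, c in plots if c != eid], dtype=float
        ).reshape(-1, 2)
        if len(own) == 0:
            (blo, bhi), (clo, chi) = by_id[eid].bounding_box()
            xlo, xhi = _snap_outward(max(blo, dxlo), min(bhi, dxhi), snr_cuts)
            ylo, yhi = _snap_outward(max(clo, dylo), min(chi, dyhi), smr_cuts)
            rect = EcositeRectangle(eid, (xlo, xhi), (ylo, yhi))
            # shrink against already-fixed rectangles if necessary
            while any(rect.overlaps(f) for f in fixed):
                shrunk, _ = _best_rectangle(
                    np.array([by_id[eid].center]).reshape(-1, 2),
                    other,
                    snr_cuts,
                    smr_cuts,
                    fixed,
                    lam,
                    domain,
                    eid,
                )
                if shrunk is None:
                    raise GridError(
                        f"no lattice rectangle available for ecosite {eid}"
                    )
                rect = shrunk
                break
        else:
            rect, _ = _best_rectangle(
                own, other, snr_cuts, smr_cuts, fixed, lam, domain, eid
            )
            if rect is None:
                raise GridError(f"no lattice rectangle available for ecosite {eid}")
        fixed.append(rect)

    if expand:
        fixed = _expand_to_partition(fixed, domain, (snr_cuts, smr_cuts))
    # return in ecosite-id order
    return sorted(fixed, key=lambda r: r.ecosite_id)


# -- point classification ------------------------------------------------


def classify_point(grid: EdatopicGrid, snr: float, smr: float) -> tuple[int, bool]:
    """Classify a continuous (SNR, SMR) point to an ecosite.

    Inputs are clamped to the grid domain.  If the point lies inside a
    rectangle its ecosite is returned with ``inside=True``; otherwise the
    nearest rectangle (Euclidean distance, ties to the lower ecosite id)
    is returned with ``inside=False``.
    """
    if math.isnan(snr) or math.isnan(smr):
        raise GridError("classify_point: NaN coordinates")
    snr, smr = grid.clamp(float(snr), float(smr))
    for rect in grid.rectangles:
        if rect.contains(snr, smr, domain=grid.domain):
            return rect.ecosite_id, True
    best = min(
        grid.rectangles, key=lambda r: (r.distance(snr, smr), r.ecosite_id)
    )
    return best.ecosite_id, False


# -- center-distance diagnostic -----------------------------------------


def grid_centers(grid: EdatopicGrid, plots, predictions) -> dict[int, dict]:
    """Per-ecosite distribution centers vs model-predicted centers.

    ``plots`` is an iterable of ``(snr, smr, ecosite_id)`` field
    assessments and ``predictions`` the per-plot predicted ``(snr, smr)``
    in the same order.  For each ecosite with at least one plot, reports
    the mean field coordinates (distribution center), the mean predicted
    coordinates of the same plots (model-predicted center) and the
    Euclidean distance between the two, in class units.
    """
    plots = list(plots)
    predictions = list(predictions)
    if len(plots) != len(predictions):
        raise GridError("plots and predictions must have equal length")
    out: dict[int, dict] = {}
    by_eco: dict[int, list[int]] = {}
    for i, (_, _, eid) in enumerate(plots):
        by_eco.setdefault(int(eid), []).append(i)
    for eid in sorted(by_eco):
        idx = by_eco[eid]
        f = np.array([[plots[i][0], plots[i][1]] for i in idx], dtype=float)
        p = np.array([list(predictions[i]) for i in idx], dtype=float)
        fc, pc = f.mean(axis=0), p.mean(axis=0)
        out[eid] = {
            "distribution_center": (float(fc[0]), float(fc[1])),
            "model_predicted_center": (float(pc[0]), float(pc[1])),
            "distance": float(np.hypot(*(fc - pc))),
            "n": len(idx),
        }
    return out


# -- configuration loading ----------------------------------------------


def _load_yaml(source) -> dict:
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    text = str(source)
    if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
        with open(text, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    return yaml.safe_load(text)


def load_grid(source) -> EdatopicGrid:
    """Load and validate an edatopic grid definition from YAML.

    Schema: ``region``, ``domain {snr: [lo,hi], smr: [lo,hi]}``,
    ``rectangles [{id, snr: [lo,hi], smr: [lo,hi]}]``, optional
    ``ellipses [{id, center: [snr,smr], semi_axes: [a,b]}]`` and optional
    ``combination_rules {original: {combined, condition?}}``.
    """
    raw = _load_yaml(source)
    if not isinstance(raw, dict):
        raise GridError("grid config must be a mapping")
    for key in ("region", "domain", "rectangles"):
        if key not in raw:
            raise GridError(f"grid config missing required key {key!r}")
    dom = raw["domain"]
    try:
        domain = (
            (float(dom["snr"][0]), float(dom["snr"][1])),
            (float(dom["smr"][0]), float(dom["smr"][1])),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise GridError(f"grid config: malformed domain ({exc})") from None
    rects = []
    for entry in raw["rectangles"]:
        try:
            rects.append(
                EcositeRectangle(
                    int(entry["id"]),
                    (float(entry["snr"][0]), float(entry["snr"][1])),
                    (float(entry["smr"][0]), float(entry["smr"][1])),
                )
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise GridError(f"grid config: malformed rectangle ({exc})") from None
    ellipses = []
    for entry in raw.get("ellipses") or []:
        try:
            ellipses.append(
                EcositeEllipse(
                    int(entry["id"]),
                    (float(entry["center"][0]), float(entry["center"][1])),
                    (float(entry["semi_axes"][0]), float(entry["semi_axes"][1])),
                )
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise GridError(f"grid config: malformed ellipse ({exc})") from None
    rules: dict[int, tuple[int, int | None]] = {}
    for oid, entry in (raw.get("combination_rules") or {}).items():
        if not isinstance(entry, dict) or "combined" not in entry:
            raise GridError(
                f"grid config: combination rule for {oid} must map to "
                "{combined, condition?}"
            )
        cond = entry.get("condition")
        rules[int(oid)] = (int(entry["combined"]), None if cond is None else int(cond))
    return EdatopicGrid(
        region=str(raw["region"]),
        domain=domain,
        rectangles=tuple(rects),
        ellipses=tuple(ellipses),
        combination_rules=rules,
    )


def load_default_grid(region: str) -> EdatopicGrid:
    """The bundled Acadian or Maritime-Boreal grid."""
    from importlib import resources

    key = region.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in _GRID_FILES:
        raise GridError(
            f"no bundled grid for region {region!r}; choose from {DEFAULT_REGIONS}"
        )
    text = resources.files("ecositemap.data").joinpath(_GRID_FILES[key]).read_text()
    return load_grid(text)
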