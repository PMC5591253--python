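"""Ordinal class systems for soil drainage, moisture and nutrient regimes.

Forest ecosystem classification in Nova Scotia rates each plot on three
ordered scales: a seven-class soil drainage scale (very poor ... very
rapidly drained), a seven-class soil moisture regime (SMR: wet ... very
dry) and a five-class soil nutrient regime (SNR: very poor ... very rich).
To combine field assessments with continuous model predictions the ordinal
classes are coded as continuous "class units": full class *k* (0-based)
carries midpoint ``k + 0.5`` and the half class between two adjacent full
classes carries the integer between their midpoints (e.g. very poor/poor
= 1.0).  This module owns those codings and the binning rules that convert
continuous values back into classes.

Binning conventions
-------------------
*Full mode* uses unit-width bins that are half-open below, ``(k, k+1]``,
with the bottom bin additionally closed at 0 (so 0.1–1.0 is the wettest
class).  *Half mode* uses the quarter-offset scheme: ``[0, 0.25]`` maps to
the first full class, then 0.5-wide upper-inclusive bins alternate between
half and full classes, the top bin absorbing the remainder of the range.
Values outside the system range are clamped by default; a strict mode
raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal

import numpy as np
import yaml

__all__ = [
    "ClassSystemError",
    "OrdinalClassSystem",
    "load_default_systems",
    "load_systems",
    "DRAINAGE",
    "SMR",
    "SNR",
]


class ClassSystemError(ValueError):
    """Raised for unknown labels, out-of-range values or bad definitions."""


def _norm(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


@dataclass(frozen=True)
class OrdinalClassSystem:
    """An ordered class list with midpoint codings and binning rules.

    Parameters
    ----------
    name:
        Identifier (``drainage``, ``smr``, ``snr`` for the bundled systems).
    classes:
        Full-class labels ordered wettest/poorest first.
    midpoints:
        One continuous class-unit value per class, strictly increasing.
    range:
        Closed interval of class-unit values the system covers.
    supports_half_classes:
        Whether half classes (labels such as ``"very poor/poor"``) are
        accepted by :meth:`class_to_value` and emitted in half-mode binning.
    """

    name: str
    classes: tuple[str, ...]
    midpoints: tuple[float, ...]
    range: tuple[float, float]
    supports_half_classes: bool = True
    _lookup: dict[str, float] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        classes = tuple(_norm(c) for c in self.classes)
        midpoints = tuple(float(m) for m in self.midpoints)
        lo, hi = (float(v) for v in self.range)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "midpoints", midpoints)
        object.__setattr__(self, "range", (lo, hi))
        if len(classes) != len(midpoints) or len(classes) < 2:
            raise ClassSystemError(
                f"system {self.name!r}: need >=2 classes with one midpoint each"
            )
        if len(set(classes)) != len(classes):
            raise ClassSystemError(f"system {self.name!r}: duplicate class labels")
        diffs = np.diff(midpoints)
        if not np.all(diffs > 0):
            raise ClassSystemError(f"system {self.name!r}: midpoints must increase")
        if midpoints[0] <= lo or midpoints[-1] >= hi:
            raise ClassSystemError(
                f"system {self.name!r}: midpoints must lie strictly inside range"
            )
        lookup = {c: m for c, m in zip(classes, midpoints)}
        if self.supports_half_classes:
            for i in range(len(classes) - 1):
                lookup[self.half_label(i)] = (midpoints[i] + midpoints[i + 1]) / 2.0
        object.__setattr__(self, "_lookup", lookup)

    # -- labels ---------------------------------------------------------

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def half_label(self, i: int) -> str:
        """Label of the half class between full classes ``i`` and ``i+1``.

        Slashes inside the component labels are replaced by hyphens so the
        separating slash stays unambiguous: the half class between ``wet``
        and ``moist/wet`` is ``"wet/moist-wet"``.
        """
        lo = self.classes[i].replace("/", "-")
        hi = self.classes[i + 1].replace("/", "-")
        return f"{lo}/{hi}"

    @property
    def half_labels(self) -> tuple[str, ...]:
        return tuple(self.half_label(i) for i in range(self.n_classes - 1))

    def index(self, label: str) -> int:
        """0-based index of a *full* class label."""
        try:
            return self.classes.index(_norm(label))
        except ValueError:
            raise ClassSystemError(
                f"system {self.name!r}: {label!r} is not a full class"
            ) from None

    def is_half_label(self, label: str) -> bool:
        return _norm(label) in self.half_labels

    # -- conversions ----------------------------------------------------

    def class_to_value(self, label: str) -> float:
        """Continuous class-unit value of a full- or half-class label."""
        key = _norm(label)
        if key not in self._lookup:
            raise ClassSystemError(
                f"system {self.name!r}: unknown class label {label!r}"
            )
        if not self.supports_half_classes and key not in self.classes:
            raise ClassSystemError(
                f"system {self.name!r}: half classes are not supported"
            )
        return self._lookup[key]

    def _clamp(self, value: float, clamp: bool) -> float:
        lo, hi = self.range
        if np.isnan(value):
            raise ClassSystemError(f"system {self.name!r}: value is NaN")
        if value < lo or value > hi:
            if not clamp:
                raise ClassSystemError(
                    f"system {self.name!r}: value {value} outside range [{lo}, {hi}]"
                )
            value = min(max(value, lo), hi)
        return value

    def value_to_class(
        self,
        value: float,
        mode: Literal["full", "half"] = "full",
        clamp: bool = True,
    ) -> str:
        """Bin a continuous class-unit value back into a class label.

        ``full`` mode bins into the full classes only; ``half`` mode may
        return half-class labels (quarter-offset scheme, see module notes).
        """
        value = self._clamp(float(value), clamp)
        lo, _ = self.range
        if mode == "full":
            # bins (k, k+1] relative to midpoints spacing 1; bottom closed
            edges = [
                (self.midpoints[i] + self.midpoints[i + 1]) / 2.0
                for i in range(self.n_classes - 1)
            ]
            j = int(np.searchsorted(edges, value, side="left"))
            return self.classes[j]
        if mode == "half":
            if not self.supports_half_classes:
                raise ClassSystemError(
                    f"system {self.name!r}: half classes are not supported"
                )
            # [lo, lo+0.25] -> full 0, then 0.5-wide upper-inclusive bins
            # alternating half/full; top bin extends to the range top.
            labels: list[str] = [self.classes[0]]
            for i in range(self.n_classes - 1):
                labels.append(self.half_label(i))
                labels.append(self.classes[i + 1])
            edges = [lo + 0.25 + 0.5 * k for k in range(len(labels) - 1)]
            j = int(np.searchsorted(edges, value, side="left"))
            return labels[j]
        raise ClassSystemError(f"unknown binning mode {mode!r}")

    def resolve_to_full(self, label: str) -> str:
        """Resolve a possibly-half class label to the nearest full class.

        Half classes are equidistant from both neighbours; the tie goes to
        the wetter/poorer (lower-index) class, matching how half-class
        field calls are collapsed before building error matrices.
        """
        key = _norm(label)
        if key in self.classes:
            return key
        if key in self.half_labels:
            return self.classes[self.half_labels.index(key)]
        raise ClassSystemError(f"system {self.name!r}: unknown class label {label!r}")

    def within_k_classes(self, a: str, b: str, k: int) -> bool:
        """True iff full classes ``a`` and ``b`` are at most ``k`` apart."""
        if k < 0:
            raise ClassSystemError("k must be >= 0")
        for lab in (a, b):
            if self.is_half_label(lab):
                raise ClassSystemError(
                    f"system {self.name!r}: +/-k tolerance is defined on full "
                    f"classes only, got half class {lab!r}"
                )
        return abs(self.index(a) - self.index(b)) <= k


# -- module-level convenience wrappers (the operation surface) -----------


def class_to_value(system: OrdinalClassSystem, label: str) -> float:
    return system.class_to_value(label)


def value_to_class(
    system: OrdinalClassSystem,
    value: float,
    mode: Literal["full", "half"] = "full",
    clamp: bool = True,
) -> str:
    return system.value_to_class(value, mode=mode, clamp=clamp)


def within_k_classes(system: OrdinalClassSystem, a: str, b: str, k: int) -> bool:
    return system.within_k_classes(a, b, k)


# -- configuration loading ----------------------------------------------


def load_systems(source) -> dict[str, OrdinalClassSystem]:
    """Load class systems from a YAML mapping ``{systems: [...]}``.

    ``source`` may be a path, an open file object or a YAML string.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
            with open(text, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        else:
            raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "systems" not in raw:
        raise ClassSystemError("class-system config must contain a 'systems' list")
    out: dict[str, OrdinalClassSystem] = {}
    for entry in raw["systems"]:
        sys_ = OrdinalClassSystem(
            name=entry["name"],
            classes=tuple(entry["classes"]),
            midpoints=tuple(entry["midpoints"]),
            range=tuple(entry["range"]),
            supports_half_classes=bool(entry.get("supports_half_classes", True)),
        )
        out[sys_.name] = sys_
    return out


def load_default_systems() -> dict[str, OrdinalClassSystem]:
    """The bundled drainage / SMR / SNR systems."""
    text = resources.files("ecositemap.data").joinpath("class_systems.yaml").read_text()
    return load_systems(text)


_DEFAULTS = load_default_systems()
DRAINAGE: OrdinalClassSystem = _DEFAULTS["drainage"]
SMR: OrdinalClassSystem = _DEFAULTS["smr"]
SNR: OrdinalClassSystem = _DEFAULTS["snr"]
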