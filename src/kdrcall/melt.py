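"""Derivative melt-curve peak detection and Tm-window call rules.

A melt-curve assay (MCA) distinguishes allele-specific PCR products by their
melting temperature.  The derivative fluorescence signal shows one peak per
product; a sample allele is called present when a peak's Tm falls within a
fixed tolerance (default +/-0.3 degC) of the Tm of the control well for that
allele, read in the same run.  Control Tm values are therefore run-supplied
data and never hard-coded; an assay may list several control Tms for one
observable class (e.g. the V and G products of the V1016I assay, which
co-melt within the calling window and form a single "V-like" class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MeltCurve",
    "TmPeak",
    "AssayDefinition",
    "McaCall",
    "ControlResult",
    "RunValidity",
    "find_peaks",
    "call_mca",
    "validate_controls",
    "default_assay_definitions",
    "read_curves_csv",
    "write_curves_csv",
]

#: float guard for the inclusive +/- tolerance comparison
_EPS = 1e-9


@dataclass(frozen=True)
class MeltCurve:
    """A baseline-subtracted derivative melt curve on a temperature grid."""

    temperatures: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("temperatures and values must be equal-length 1-D arrays")
        if t.size < 50:
            raise ValueError(f"curve needs >= 50 points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("derivative values must be nonnegative")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.temperatures)))


@dataclass(frozen=True)
class TmPeak:
    """A detected derivative peak."""

    tm: float
    height: float
    prominence: float

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


@dataclass(frozen=True)
class AssayDefinition:
    """Calling parameters for one melt-curve assay.

    ``class_tms`` maps each observable class to the Tm(s) of its control
    well(s).  A class carries several control Tms when several alleles map to
    it (one control per allele, after the recommendation to control every
    possible allele).  Classes whose control Tms sit closer than twice the
    tolerance must be declared in ``confusable_classes``.
    """

    assay_id: str
    class_tms: Mapping[str, tuple[float, ...]]
    tolerance: float = 0.3
    min_rel_height: float = 0.2
    confusable_classes: frozenset[frozenset[str]] = frozenset()

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        tms = {
            cls: tuple(float(t) for t in ts) for cls, ts in dict(self.class_tms).items()
        }
        object.__setattr__(self, "class_tms", tms)
        classes = list(tms)
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                gap = min(abs(x - y) for x in tms[a] for y in tms[b])
                if gap <= 2 * self.tolerance and frozenset((a, b)) not in self.confusable_classes:
                    raise ValueError(
                        f"{self.assay_id}: classes {a}/{b} controls only {gap:.2f} C "
                        "apart; declare them confusable or separate them"
                    )

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.class_tms)


@dataclass(frozen=True)
class McaCall:
    """Result of calling one sample in one melt-curve assay."""

    assay_id: str
    detected_classes: frozenset[str]
    status: str  # "called" | "no_call"
    no_call_reason: str | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "called") != bool(self.detected_classes):
            raise ValueError("detected_classes must be nonempty iff status == 'called'")

    @property
    def is_heterozygous_pattern(self) -> bool:
        return len(self.detected_classes) >= 2


def default_assay_definitions() -> dict[str, AssayDefinition]:
    """Packaged fixture assay definitions for the three MCAs.

    Only the +/-0.3 degC window and the 0.8 degC I-below-V product offset in
    the V1016G assay reflect measured behaviour; the absolute Tm values are
    fixture constants standing in for run-specific control wells.  In the
    V1016I assay the G product co-melts with the V product (0.2 degC above,
    inside the window), which is exactly the confusability the assay exhibits.
    """
    return {
        "V1016I_MCA": AssayDefinition(
            "V1016I_MCA",
            # V control 79.0 and G control 79.2 both define the V-like class.
            class_tms={"Vclass": (79.0, 79.2), "Iclass": (81.0,)},
        ),
        "V1016G_MCA": AssayDefinition(
            "V1016G_MCA",
            # non-G class controlled by both the V (84.0) and I (83.2) wells.
            class_tms={"Gclass": (80.0,), "nonG": (84.0, 83.2)},
        ),
        "F1534C_MCA": AssayDefinition(
            "F1534C_MCA",
            class_tms={"Fclass": (86.0,), "Cclass": (84.5,)},
        ),
    }


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    # reflect-pad so the moving average stays centred at the edges
    pad = window // 2
    padded = np.concatenate([values[pad:0:-1], values, values[-2 : -2 - pad : -1]])
    return np.convolve(padded, kernel, mode="valid")


def _refine_tm(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Parabolic interpolation of the peak apex around grid index ``i``."""
    if i == 0 or i == len(v) - 1:
        return float(t[i])
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    if denom >= 0:
        return float(t[i])
    delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
    step = t[i + 1] - t[i]
    return float(t[i] + np.clip(delta, -1, 1) * step)


def find_peaks(
    curve: MeltCurve,
    min_rel_height: float = 0.2,
    smooth_window: int = 5,
    min_abs_height: float = 0.05,
    max_peaks: int = 3,
) -> list[TmPeak]:
    """Detect up to ``max_peaks`` derivative peaks, tallest first.

    The curve is lightly smoothed (centred moving average, ``smooth_window``
    grid points) before local maxima are taken; peaks below
    ``min_rel_height`` x the global maximum, or below the absolute noise
    floor ``min_abs_height``, are discarded.  Tm is refined off-grid by
    parabolic interpolation, so a symmetric peak's Tm is recovered to well
    within one grid step.
    """
    sm = _smooth(curve.values, smooth_window)
    top = float(sm.max(initial=0.0))
    if top <= min_abs_height:
        return []
    threshold = min_rel_height * top
    idx, props = signal.find_peaks(sm, height=threshold, prominence=0.5 * threshold)
    peaks = [
        TmPeak(
            tm=_refine_tm(curve.temperatures, sm, int(i)),
            height=float(sm[i]),
            prominence=float(p),
        )
        for i, p in zip(idx, props["prominences"])
    ]
    peaks.sort(key=lambda p: p.height, reverse=True)
    return peaks[:max_peaks]


def _nearest_class(peak: TmPeak, assay: AssayDefinition) -> tuple[str | None, list[str]]:
    """Return (nearest in-window class or None, all in-window classes)."""
    in_window: list[tuple[float, str]] = []
    for cls, tms in assay.class_tms.items():
        dist = min(abs(peak.tm - t) for t in tms)
        if dist <= assay.tolerance + _EPS:
            in_window.append((dist, cls))
    if not in_window:
        return None, []
    in_window.sort()
    return in_window[0][1], [cls for _, cls in in_window]


def call_mca(peaks: Sequence[TmPeak], assay: AssayDefinition) -> McaCall:
    """Assign peaks to observable classes by the +/- tolerance window rule.

    Each peak is given the class whose control Tm is within tolerance
    (nearest control wins when two classes qualify, with a warning); peaks
    matching no control are ignored with a warning.  One assigned class is a
    homozygous pattern, two a heterozygous pattern; no assignable peak is a
    no-call.
    """
    if not peaks:
        return McaCall(assay.assay_id, frozenset(), "no_call", "no amplification")
    detected: set[str] = set()
    warnings: list[str] = []
    for peak in peaks:
        cls, candidates = _nearest_class(peak, assay)
        if cls is None:
            warnings.append(f"peak at {peak.tm:.2f} C matches no control (ignored)")
        else:
            if len(candidates) > 1:
                warnings.append(
                    f"peak at {peak.tm:.2f} C within tolerance of classes "
                    f"{sorted(candidates)}; nearest ({cls}) assigned"
                )
            detected.add(cls)
    if not detected:
        return McaCall(
            assay.assay_id,
            frozenset(),
            "no_call",
            "no peak within tolerance",
            tuple(warnings),
        )
    return McaCall(assay.assay_id, frozenset(detected), "called", None, tuple(warnings))


@dataclass(frozen=True)
class ControlResult:
    control: str
    ok: bool
    message: str


@dataclass(frozen=True)
class RunValidity:
    """Outcome of control-based run validation.

    ``status`` is ``valid``, ``valid_with_warning`` (a heterozygous control
    failed: the run is usable but competitive-primer balance is suspect) or
    ``invalid`` (a homozygous or negative control failed, or a control is
    absent).
    """

    status: str
    results: tuple[ControlResult, ...] = ()

    @property
    def failures(self) -> tuple[ControlResult, ...]:
        return tuple(r for r in self.results if not r.ok)


def validate_controls(
    control_calls: Mapping[str, McaCall],
    expected: Mapping[str, frozenset[str] | None],
    assay: AssayDefinition,
) -> RunValidity:
    """Validate a run from its control wells.

    ``expected`` maps each control name to the class set it must produce
    (one class for homozygous controls, two for heterozygous mixes, ``None``
    or empty for the negative).  A valid run has every homozygous control
    yielding exactly its class, every heterozygous control both classes, and
    the negative a no-call.  A failed heterozygous control downgrades the run
    to ``valid_with_warning``; anything else failing invalidates it.
    """
    results: list[ControlResult] = []
    status = "valid"

    def downgrade(to: str) -> None:
        nonlocal status
        order = ["valid", "valid_with_warning", "invalid"]
        if order.index(to) > order.index(status):
            status = to

    for name, want in expected.items():
        call = control_calls.get(name)
        if call is None:
            results.append(ControlResult(name, False, "control absent"))
            downgrade("invalid")
            continue
        if not want:  # negative control
            if call.status == "no_call":
                results.append(ControlResult(name, True, "negative gave no call"))
            else:
                results.append(
                    ControlResult(
                        name,
                        False,
                        f"negative control amplified: {sorted(call.detected_classes)}",
                    )
                )
                downgrade("invalid")
            continue
        if call.status == "called" and call.detected_classes == want:
            results.append(ControlResult(name, True, "as expected"))
            continue
        got = sorted(call.detected_classes) if call.status == "called" else "no call"
        results.append(
            ControlResult(name, False, f"expected {sorted(want)}, got {got}")
        )
        downgrade("valid_with_warning" if len(want) >= 2 else "invalid")
    return RunValidity(status, tuple(results))


def write_curves_csv(curves, path_or_buf) -> None:
    """Write curves as long-format CSV (sample_id, assay_id, temperature_C,
    derivative).  ``curves`` maps (sample_id, assay_id) to a MeltCurve."""
    import pandas as pd

    frames = []
    for (sample_id, assay_id), curve in curves.items():
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "assay_id": assay_id,
                    "temperature_C": curve.temperatures,
                    "derivative": curve.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path_or_buf, index=False)


def read_curves_csv(path_or_buf) -> dict[tuple[str, str], MeltCurve]:
    """Read long-format curves CSV back into MeltCurve objects per
    (sample_id, assay_id) well."""
    import pandas as pd

    df = pd.read_csv(path_or_buf)
    out: dict[tuple[str, str], MeltCurve] = {}
    for (sample_id, assay_id), grp in df.groupby(["sample_id", "assay_id"], sort=False):
        grp = grp.sort_values("temperature_C")
        out[(str(sample_id), str(assay_id))] = MeltCurve(
            grp["temperature_C"].to_numpy(), grp["derivative"].to_numpy()
        )
    return out
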