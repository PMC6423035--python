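"""Reduction of quasi-static tensile tests on nest material.

Force-displacement records become engineering stress-strain curves
(sigma = F/A0, eps = dL/L0 — initial cross-section and gauge length, no
smoothing), from which the elastic modulus (OLS slope over the linear
regime), the fracture stress (peak stress) and the strain to fracture are
extracted.  Specimens are cut at 0 deg (longitudinal, along the saliva
fibers), 45 deg and 90 deg (transverse); cohorts are aggregated overall and
per cut orientation.

The "linear regime" of the modulus fit is bracketed as
eps in [0.002, eps at 0.5 * peak stress]: the lower bound skips the seating
toe, the upper bound stays clear of the nonlinear branch.  Both bounds are
parameters; when the default window holds fewer than 5 samples the fit
falls back to the first half of the pre-peak range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_DISP_UNIT_TO_MM = {"mm": 1.0, "um": 1e-3, "μm": 1e-3}

#: CSV column layout for specimen tables.
CSV_COLUMNS = ("specimen_id", "force_N", "displacement_um",
               "A0_mm2", "L0_mm", "cut_angle_deg")


@dataclass
class TensileRecord:
    """One specimen's raw force-displacement record."""

    force: np.ndarray            # N
    displacement: np.ndarray     # in `displacement_unit`
    A0: float                    # initial cross-section, mm^2
    L0: float                    # gauge length, mm
    cut_angle: float = 0.0       # degrees: 0 longitudinal, 45, 90 transverse
    specimen_id: str = ""
    displacement_unit: str = "um"

    def __post_init__(self):
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement_unit not in _DISP_UNIT_TO_MM:
            raise ValueError(
                f"displacement unit must be tagged as one of "
                f"{sorted(set(_DISP_UNIT_TO_MM))}, got {self.displacement_unit!r}"
            )
        if self.force.shape != self.displacement.shape or self.force.ndim != 1:
            raise ValueError("force and displacement must be equal-length 1D series")
        if len(self.force) < 3:
            raise ValueError("need at least 3 samples")
        if self.A0 <= 0 or self.L0 <= 0:
            raise ValueError("A0 and L0 must be positive")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")


@dataclass
class StressStrainCurve:
    stress: np.ndarray           # MPa
    strain: np.ndarray           # dimensionless
    E: float = None              # MPa
    sigma_peak: float = None     # MPa
    eps_fracture: float = None
    fit_window: tuple = None     # (eps_lo, eps_hi) actually used
    cut_angle: float = 0.0
    specimen_id: str = ""
    fracture_reached: bool = True
    drop_events: list = field(default_factory=list)


def to_stress_strain(rec: TensileRecord) -> StressStrainCurve:
    """Engineering stress-strain: sigma_i = F_i/A0 (MPa for N and mm^2),
    eps_i = dL_i/L0. No smoothing is applied."""
    scale = _DISP_UNIT_TO_MM[rec.displacement_unit]
    stress = rec.force / rec.A0
    strain = rec.displacement * scale / rec.L0
    return StressStrainCurve(stress=stress, strain=strain,
                             cut_angle=rec.cut_angle,
                             specimen_id=rec.specimen_id)


def extract_modulus(curve: StressStrainCurve, eps_toe: float = 0.002,
                    peak_fraction: float = 0.5) -> float:
    """Elastic modulus: OLS slope of stress on strain over the linear regime.

    Window: strain in [eps_toe, strain where stress first reaches
    peak_fraction * peak] restricted to the pre-peak branch; falls back to
    the first half of the pre-peak range when fewer than 5 samples land in
    the window. The window used is recorded on the curve.
    """
    sigma, eps = curve.stress, curve.strain
    i_peak = int(np.argmax(sigma))
    sigma_peak = sigma[i_peak]
    pre = slice(0, i_peak + 1)
    reach = np.flatnonzero(sigma[pre] >= peak_fraction * sigma_peak)
    eps_hi = eps[reach[0]] if reach.size else eps[i_peak]
    sel = (eps >= eps_toe) & (eps <= eps_hi)
    sel[i_peak + 1:] = False
    if sel.sum() < 5:
        # first half of the pre-peak strain range
        eps_hi = eps[0] + 0.5 * (eps[i_peak] - eps[0])
        sel = np.zeros_like(sel)
        sel[:i_peak + 1] = eps[:i_peak + 1] <= eps_hi
    x, ysel = eps[sel], sigma[sel]
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate modulus window (constant strain)")
    E = float(np.polyfit(x, ysel, 1)[0])
    curve.E = E
    curve.fit_window = (float(x.min()), float(x.max()))
    return E


def detect_failure(curve: StressStrainCurve, fail_fraction: float = 0.1,
                   drop_fraction: float = 0.05):
    """Peak stress, strain to fracture and post-peak stress-drop events.

    Fracture strain is the strain at the first post-peak sample where stress
    falls below ``fail_fraction`` of the peak; if the record ends before
    that, the final strain is reported and the curve is flagged as not
    having reached fracture.  Drop events are post-peak decreases between
    consecutive samples exceeding ``drop_fraction`` of the peak — the
    signature of individual fibers failing before ultimate failure.
    """
    sigma, eps = curve.stress, curve.strain
    i_peak = int(np.argmax(sigma))
    sigma_peak = float(sigma[i_peak])
    post = sigma[i_peak:]
    below = np.flatnonzero(post < fail_fraction * sigma_peak)
    if below.size:
        eps_fracture = float(eps[i_peak + below[0]])
        reached = True
    else:
        eps_fracture = float(eps[-1])
        reached = False
    deltas = np.diff(sigma[i_peak:])
    drops = np.flatnonzero(deltas < -drop_fraction * sigma_peak) + i_peak
    curve.sigma_peak = sigma_peak
    curve.eps_fracture = eps_fracture
    curve.fracture_reached = reached
    curve.drop_events = [(int(i), float(-deltas[i - i_peak])) for i in drops]
    return sigma_peak, eps_fracture, curve.drop_events


def reduce_record(rec: TensileRecord) -> StressStrainCurve:
    """Full per-specimen reduction: curve, modulus, failure metrics."""
    curve = to_stress_strain(rec)
    detect_failure(curve)
    extract_modulus(curve)
    return curve


@dataclass
class MaterialSummary:
    mean_sigma_f: float
    sd_sigma_f: float
    mean_E: float
    sd_E: float
    n_specimens: int
    by_orientation: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "by_orientation"}
        return pd.DataFrame([d])


def aggregate(curves: list) -> MaterialSummary:
    """Unweighted mean / sample SD (ddof=1) of peak stress and modulus,
    overall and per cut orientation. For a single specimen the SD is
    reported as 0.0 by convention."""
    if not curves:
        raise ValueError("no curves to aggregate")
    rows = []
    for c in curves:
        if c.sigma_peak is None:
            detect_failure(c)
        if c.E is None:
            extract_modulus(c)
        rows.append({"cut_angle_deg": c.cut_angle, "sigma_f_MPa": c.sigma_peak,
                     "E_MPa": c.E, "specimen_id": c.specimen_id})
    df = pd.DataFrame(rows)

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    by = (df.groupby("cut_angle_deg")
            .agg(mean_sigma_f=("sigma_f_MPa", "mean"),
                 sd_sigma_f=("sigma_f_MPa", _sd),
                 mean_E=("E_MPa", "mean"),
                 sd_E=("E_MPa", _sd),
                 n=("sigma_f_MPa", "size"))
            .reset_index())
    return MaterialSummary(
        mean_sigma_f=float(df.sigma_f_MPa.mean()),
        sd_sigma_f=_sd(df.sigma_f_MPa),
        mean_E=float(df.E_MPa.mean()),
        sd_E=_sd(df.E_MPa),
        n_specimens=len(df),
        by_orientation=by,
    )


def load_records(path) -> list:
    """Read specimen records from a long-format CSV (columns CSV_COLUMNS,
    one row per sample, grouped by specimen_id)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"specimen CSV missing columns: {sorted(missing)}")
    records = []
    for sid, g in df.groupby("specimen_id", sort=False):
        records.append(TensileRecord(
            force=g.force_N.to_numpy(),
            displacement=g.displacement_um.to_numpy(),
            A0=float(g.A0_mm2.iloc[0]),
            L0=float(g.L0_mm.iloc[0]),
            cut_angle=float(g.cut_angle_deg.iloc[0]),
            specimen_id=str(sid),
            displacement_unit="um",
        ))
    return records


def save_records(records: list, path) -> None:
    frames = []
    for r in records:
        if r.displacement_unit != "um":
            disp_um = r.displacement * _DISP_UNIT_TO_MM[r.displacement_unit] * 1e3
        else:
            disp_um = r.displacement
        frames.append(pd.DataFrame({
            "specimen_id": r.specimen_id, "force_N": r.force,
            "displacement_um": disp_um, "A0_mm2": r.A0, "L0_mm": r.L0,
            "cut_angle_deg": r.cut_angle,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def synthesize_specimen(sigma_peak: float, E: float, eps_fracture: float = 0.125,
                        cut_angle: float = 0.0, n_drops: int = 3,
                        A0: float = 1.5, L0: float = 10.0,
                        n_samples: int = 400, seed: int = 0,
                        specimen_id: str = "synthetic") -> TensileRecord:
    """Generate a synthetic 'tough'-type specimen record.

    Linear rise at modulus E to ~60% of the peak, a softening parabolic cap
    to the peak, ``n_drops`` discrete post-peak stress drops (individual
    fiber failures), then a cliff to zero at ``eps_fracture``.  Deterministic
    for a given seed; used by tests and the demo CLI, not a measurement.
    """
    rng = np.random.default_rng(seed)
    eps_lin = 0.6 * sigma_peak / E
    eps_peak = min(1.8 * eps_lin, 0.9 * eps_fracture)
    eps = np.linspace(0.0, eps_fracture * 1.04, n_samples)
    sigma = np.empty_like(eps)
    rise = eps <= eps_lin
    sigma[rise] = E * eps[rise]
    cap = (eps > eps_lin) & (eps <= eps_peak)
    # parabola through (eps_lin, 0.6 peak) with apex (eps_peak, peak)
    a = 0.4 * sigma_peak / (eps_peak - eps_lin) ** 2
    sigma[cap] = sigma_peak - a * (eps[cap] - eps_peak) ** 2
    tail = eps > eps_peak
    level = np.full(tail.sum(), 0.9 * sigma_peak)
    drop_at = np.sort(rng.choice(np.arange(2, tail.sum() - 2), size=n_drops,
                                 replace=False))
    for i, d in enumerate(drop_at):
        level[d:] -= (0.12 + 0.04 * i) * sigma_peak
    sigma[tail] = np.maximum(level, 0.05 * sigma_peak)
    sigma[eps >= eps_fracture] = 0.0
    force = sigma * A0
    disp_um = eps * L0 * 1e3
    return TensileRecord(force=force, displacement=disp_um, A0=A0, L0=L0,
                         cut_angle=cut_angle, specimen_id=specimen_id)


def synthesize_cohort(n: int = 30, mean_peak: float = 2.75, sd_peak: float = 0.79,
                      mean_E: float = 155.0, seed: int = 7) -> list:
    """A seeded cohort of synthetic specimens with normally distributed peak
    stresses (truncated at 0.2 MPa) across the three cut orientations."""
    rng = np.random.default_rng(seed)
    peaks = np.maximum(rng.normal(mean_peak, sd_peak, n), 0.2)
    Es = np.maximum(rng.normal(mean_E, 0.1 * mean_E, n), 10.0)
    angles = [0.0, 45.0, 90.0]
    return [
        synthesize_specimen(float(pk), float(e), cut_angle=angles[i % 3],
                            seed=int(rng.integers(2 ** 31)),
                            specimen_id=f"S{i:03d}")
        for i, (pk, e) in enumerate(zip(peaks, Es))
    ]
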