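"""Loading scenarios for a segmented or phantom nest.

Encodes the natural loading cases of a wall-anchored half-cup nest:

* ``worst_case`` — two adult birds standing on the rim (cuboid footprints
  placed on the outermost rim band, symmetrically about the front midline to
  maximize the bending moment on the wall fixation) plus two eggs resting on
  the cup floor (elliptic contact patches), with gravity self-weight;
* ``eggs_only`` — the two egg loads alone, to isolate their contribution;
* ``damaged`` — the worst case on a geometry with spherical damage sites
  removed.

Each bird weighs 16 g and each egg 1.2 g; weights convert to forces under
standard gravity with 4-decimal truncation, giving 0.1569 N and 0.0117 N.
All loads act downward (-U-D).  Reports carry per-region stress statistics
(rim band, egg region, anchor band — reporting conventions that never enter
the solve) and the safety factor against the material's tensile fracture
strength (default 2.75 MPa), which enters only as a post-hoc threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .voxfem import (FEError, FEModel, LoadROI, MaterialModel,
                     apply_damage, build_model, solve)
from .volume_io import MaskVolume, VoxelVolume

BIRD_MASS_G = 16.0
EGG_MASS_G = 1.2
STANDARD_GRAVITY_M_S2 = 9.80665


def mass_to_force(mass_g: float, decimals: int = 4) -> float:
    """Weight (N) of a mass in grams under standard gravity, truncated (not
    rounded) to ``decimals`` decimal places: 16 g -> 0.1569 N,
    1.2 g -> 0.0117 N."""
    w = mass_g * 1e-3 * STANDARD_GRAVITY_M_S2
    factor = 10 ** decimals
    return math.floor(w * factor) / factor


BIRD_FORCE_N = mass_to_force(BIRD_MASS_G)   # 0.1569
EGG_FORCE_N = mass_to_force(EGG_MASS_G)     # 0.0117


@dataclass
class ScenarioConfig:
    """Geometric conventions of the loading scenarios (mm / MPa).

    The original study gives the ROI shapes (cuboids for birds, ellipses for
    eggs) but not their sizes or exact placement; these defaults are
    package conventions, all configurable.  Birds sit at +-20 deg from the
    front midline: close enough to the front to apply a near-maximal
    bending moment on the wall fixation (the moment arm is the B-F distance
    from the wall, largest at the midline) while keeping two distinct,
    symmetric footprints.
    """

    bird_footprint: tuple = (5.0, 5.0)     # (B-F, R-L) mm
    egg_patch: tuple = (10.0, 6.0)         # plan ellipse axes (B-F, R-L) mm
    bird_angle_deg: float = 20.0           # from the front midline, each side
    egg_offset_rl: float = 8.0             # egg centers at +- offset, mm
    rim_band_frac: float = 0.10            # top fraction of U-D extent
    anchor_band_frac: float = 0.10         # B-F fraction nearest the wall
    fracture_strength: float = 2.75        # MPa, reporting threshold only
    bird_force: float = BIRD_FORCE_N
    egg_force: float = EGG_FORCE_N
    n_birds: int = 2
    n_eggs: int = 2


@dataclass
class RegionStats:
    mean: float
    max: float
    n_elements: int


@dataclass
class ScenarioReport:
    scenario: str
    global_max_principal: float            # MPa
    max_location_element: int
    max_location_mm: tuple
    region_stats: dict                     # name -> RegionStats
    safety_factor: float                   # inf flag when stress <= 0
    safety_infinite: bool
    fracture_strength: float
    total_applied_force_N: tuple
    iterations: int
    residual: float
    n_elements: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_stats"] = {k: asdict(v) if isinstance(v, RegionStats) else v
                             for k, v in self.region_stats.items()}
        return d


# ---------------------------------------------------------------------------
# geometric placement
# ---------------------------------------------------------------------------

def _surface_up_voxels(mask: np.ndarray) -> np.ndarray:
    up = np.empty_like(mask)
    up[-1] = mask[-1]
    up[:-1] = mask[:-1] & ~mask[1:]
    return np.argwhere(up)


def _rim_and_floor(mask: MaskVolume, config: ScenarioConfig):
    """Locate the rim band and the cup-floor low point.

    Rim band: material in the top ``rim_band_frac`` of the occupied U-D
    extent.  Cup floor: the lowest upward-exposed material voxel in the
    central plan region (away from rim and wall), where eggs come to rest.
    """
    m = mask.data
    occ = np.flatnonzero(m.any(axis=(1, 2)))
    if occ.size == 0:
        raise FEError("empty mask")
    u_lo, u_hi = occ[0], occ[-1]
    extent = u_hi - u_lo + 1
    rim_start = u_hi - max(1, int(round(config.rim_band_frac * extent))) + 1

    surf = _surface_up_voxels(m)
    if surf.size == 0:
        raise FEError("degenerate geometry: no upward-exposed surface")

    ks = np.argwhere(m.any(axis=(0, 1))).ravel()
    l_center = 0.5 * (ks[0] + ks[-1])
    js = np.argwhere(m.any(axis=(0, 2))).ravel()
    depth = js[-1] + 1

    central = surf[
        (np.abs(surf[:, 2] - l_center) < 0.3 * (ks[-1] - ks[0] + 1))
        & (surf[:, 1] > 0.15 * depth) & (surf[:, 1] < 0.85 * depth)
        & (surf[:, 0] < rim_start)
    ]
    if central.size == 0:
        raise FEError("cup floor detection failed: no central floor surface")
    floor = central[np.lexsort((central[:, 2], central[:, 1], central[:, 0]))][0]
    return rim_start, floor, (l_center, depth)


def _bird_rois(mask: MaskVolume, rim_start: int, plan_center,
               config: ScenarioConfig) -> list:
    """Cuboid bird footprints on the outermost rim band, at +-bird_angle
    from the front midline (plan angle measured about the wall-side cup
    center), each carrying one bird weight downward."""
    m = mask.data
    s = mask.spacing
    l_center, _depth = plan_center
    rim_vox = _surface_up_voxels(m)
    rim_vox = rim_vox[rim_vox[:, 0] >= rim_start]
    if rim_vox.size == 0:
        raise FEError("rim detection failed: no surface voxels in the rim band")

    rois = []
    angles = [config.bird_angle_deg, -config.bird_angle_deg][:config.n_birds] \
        if config.n_birds <= 2 else list(
            np.linspace(-75, 75, config.n_birds))
    for i, ang in enumerate(angles):
        a = np.radians(ang)
        d = np.array([np.cos(a), np.sin(a)])   # (B-F, R-L) plan direction
        proj = rim_vox[:, 1] * d[0] + (rim_vox[:, 2] - l_center) * d[1]
        best = rim_vox[int(np.argmax(proj))]
        center = ((best[0] + 0.5) * s, (best[1] + 0.5) * s, (best[2] + 0.5) * s)
        rois.append(LoadROI(
            name=f"bird_{i + 1}",
            force=np.array([-config.bird_force, 0.0, 0.0]),
            kind="cuboid", center=center, size=config.bird_footprint,
        ))
    return rois


def _egg_rois(mask: MaskVolume, floor_vox, config: ScenarioConfig) -> list:
    s = mask.spacing
    rois = []
    offs = [config.egg_offset_rl, -config.egg_offset_rl][:config.n_eggs] \
        if config.n_eggs <= 2 else list(
            np.linspace(-2, 2, config.n_eggs) * config.egg_offset_rl)
    for i, off in enumerate(offs):
        center = ((floor_vox[0] + 0.5) * s, (floor_vox[1] + 0.5) * s,
                  (floor_vox[2] + 0.5) * s + off)
        rois.append(LoadROI(
            name=f"egg_{i + 1}",
            force=np.array([-config.egg_force, 0.0, 0.0]),
            kind="ellipse", center=center, size=config.egg_patch,
        ))
    return rois


SCENARIOS = ("worst_case", "eggs_only", "birds_only", "damaged")


def make_scenario(name: str, mask: MaskVolume, gray: VoxelVolume | None = None,
                  material: MaterialModel | None = None,
                  config: ScenarioConfig | None = None,
                  damage_sites: list | None = None):
    """Build the FE model for a named scenario.

    Returns ``(FEModel, placement)`` where placement records the resolved
    rim band, floor point and ROIs (reused for region statistics).
    ``damaged`` applies :func:`nestmech.voxfem.apply_damage` to the mask
    first and then loads it as the worst case.
    """
    if name not in SCENARIOS:
        raise FEError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    config = config or ScenarioConfig()
    material = material or MaterialModel(total_mass_g=5.93)

    if name == "damaged":
        if not damage_sites:
            raise FEError("damaged scenario requires damage_sites")
        mask = apply_damage(mask, damage_sites)

    rim_start, floor, plan_center = _rim_and_floor(mask, config)
    rois = []
    if name in ("worst_case", "birds_only", "damaged"):
        rois += _bird_rois(mask, rim_start, plan_center, config)
    if name in ("worst_case", "eggs_only", "damaged"):
        rois += _egg_rois(mask, floor, config)

    model = build_model(mask, gray, material, pin_axis="B-F", pin_face=0,
                        load_rois=rois)
    placement = {
        "rim_start_index": int(rim_start),
        "floor_voxel": tuple(int(v) for v in floor),
        "rois": rois,
        "config": config,
        "mask": mask,
    }
    return model, placement


def _region_masks(model: FEModel, placement) -> dict:
    """Element selectors for the rim band, egg region and anchor band.

    Egg region: elements whose plan position falls inside an egg patch
    dilated by 1.5x.  These are reporting conventions only.
    """
    config: ScenarioConfig = placement["config"]
    idx = model.elem_index
    s = model.spacing

    u_lo, u_hi = idx[:, 0].min(), idx[:, 0].max()
    extent = u_hi - u_lo + 1
    rim_start = u_hi - max(1, int(round(config.rim_band_frac * extent))) + 1
    rim = idx[:, 0] >= rim_start

    depth = idx[:, 1].max() + 1
    anchor = idx[:, 1] < max(1, int(round(config.anchor_band_frac * depth)))

    egg = np.zeros(len(idx), dtype=bool)
    fl = placement["floor_voxel"]
    scale = placement.get("egg_region_dilation", 1.5)
    for off in (config.egg_offset_rl, -config.egg_offset_rl):
        cy = (fl[1] + 0.5) * s
        cl = (fl[2] + 0.5) * s + off
        ay = scale * config.egg_patch[0] / 2.0
        al = scale * config.egg_patch[1] / 2.0
        y = (idx[:, 1] + 0.5) * s
        l = (idx[:, 2] + 0.5) * s
        egg |= ((y - cy) / ay) ** 2 + ((l - cl) / al) ** 2 <= 1.0
    return {"rim_band": rim, "egg_region": egg, "anchor_band": anchor}


def run_scenario(model: FEModel, placement, scenario_name: str = "scenario",
                 fracture_strength: float | None = None,
                 gravity: bool = True) -> ScenarioReport:
    """Solve a scenario model and report region statistics and the safety
    factor against fracture strength."""
    config: ScenarioConfig = placement["config"]
    if fracture_strength is None:
        fracture_strength = config.fracture_strength

    field_ = solve(model, gravity=gravity)
    smax = field_.max_principal
    gmax = float(smax.max())
    e_at = int(np.argmax(smax))
    loc = tuple((model.elem_index[e_at] + 0.5) * model.spacing)

    regions = {}
    for name, sel in _region_masks(model, placement).items():
        if sel.any():
            regions[name] = RegionStats(float(smax[sel].mean()),
                                        float(smax[sel].max()), int(sel.sum()))
        else:
            regions[name] = RegionStats(float("nan"), float("nan"), 0)

    infinite = gmax <= 0.0
    sf = float("inf") if infinite else fracture_strength / gmax
    return ScenarioReport(
        scenario=scenario_name,
        global_max_principal=gmax,
        max_location_element=e_at,
        max_location_mm=loc,
        region_stats=regions,
        safety_factor=sf,
        safety_infinite=infinite,
        fracture_strength=fracture_strength,
        total_applied_force_N=tuple(model.total_applied_force(gravity=gravity)),
        iterations=field_.iterations,
        residual=field_.residual,
        n_elements=model.n_elements,
    ), field_


def compare_scenarios(reports: list) -> pd.DataFrame:
    """Side-by-side scenario table with max-stress ratios to the first
    report (e.g. eggs_only / worst_case)."""
    if len(reports) < 2:
        raise FEError("need at least two reports to compare")
    n0 = reports[0].n_elements
    rows = []
    for r in reports:
        if r.n_elements != n0 and r.scenario != "damaged":
            raise FEError("reports come from different geometries")
        row = {"scenario": r.scenario,
               "global_max_MPa": r.global_max_principal,
               "safety_factor": r.safety_factor,
               "max_ratio_to_first":
                   r.global_max_principal / reports[0].global_max_principal
                   if reports[0].global_max_principal else float("nan")}
        for name, st in r.region_stats.items():
            row[f"{name}_mean_MPa"] = st.mean
            row[f"{name}_max_MPa"] = st.max
        rows.append(row)
    return pd.DataFrame(rows)
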