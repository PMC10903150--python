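"""Synthetic paired-CT phantoms and cohorts with known ground truth.

The phantom generator plants PRM class structure inside an ellipsoidal
"lung": fSAD appears as spherical pockets whose spatial arrangement is
governed by a ``coalescence`` parameter — at 0 the pockets are disjoint
(positive Euler characteristic, one per pocket), while values near 1 draw
the pocket centres into a dense cluster whose overlapping spheres form a
mesh threaded by tunnels (negative Euler characteristic).  HU values are
sampled uniformly inside each class's admissible (inspiration, expiration)
HU rectangle, shrunk by a margin of ``0.5 + 3 * hu_noise_sd`` HU, so that a
zero-noise phantom is recovered exactly by PRM classification.

The cohort generator emulates the structure of a smoking-cohort table:
GOLD-graded spirometry, demographics, a 5-year FEV1 follow-up with fast
(<= -60 ml/yr) and slow progressor labels, and per-subject phantom
parameters (fSAD burden and coalescence) whose fast/slow separation is
controlled by ``effect_size`` in pooled-SD units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prm import CLASS_CODES, PairedCT, PRMMap, percent_volume

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "shape_phantoms",
    "focus_mask",
    "nested_lesion_phantom",
    "generate_regression_cohort",
]

# admissible (lo, hi) HU intervals per class; open/closed ends are irrelevant
# to the generator because samples are kept strictly inside by a margin.
_HU_RECTS = {
    "Norm": ((-950.0, -810.0), (-856.0, -250.0)),
    "fSAD": ((-950.0, -810.0), (-1000.0, -856.0)),
    "Emph": ((-1000.0, -950.0), (-1000.0, -856.0)),
    "PD": ((-810.0, -250.0), (-1000.0, -250.0)),
}


@dataclass
class PhantomSpec:
    """Parameters of one paired-CT phantom.

    ``class_fractions`` are target fractions of the lung per PRM class;
    the remainder is Norm.  If ``n_fsad_pockets`` is given it overrides the
    fSAD fraction and exactly that many pockets are planted.  The lesion
    focus restricts fSAD/Emph pockets to a sub-ellipsoid of the lung
    (radius as a fraction of the lung semi-axes, centre offset in units of
    the semi-axes), so that abnormality can be spatially localised.
    """

    grid_shape: tuple[int, int, int] = (45, 45, 45)
    spacing_mm: tuple[float, float, float] = (0.65, 0.65, 0.65)
    lung_axes_frac: tuple[float, float, float] = (0.45, 0.45, 0.45)
    class_fractions: dict[str, float] = field(default_factory=dict)
    n_fsad_pockets: int | None = None
    pocket_radius_vox: int = 3
    coalescence: float = 0.0
    focus_radius_frac: float = 1.0
    focus_center_frac: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hu_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n < 45 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 45 per axis")
        if self.pocket_radius_vox < 1:
            raise ValueError("pocket_radius_vox must be >= 1")
        if not 0.0 <= self.coalescence <= 1.0:
            raise ValueError("coalescence must lie in [0, 1]")
        if self.hu_noise_sd < 0:
            raise ValueError("hu_noise_sd must be >= 0")
        bad = set(self.class_fractions) - set(CLASS_CODES)
        if bad:
            raise ValueError(f"unknown PRM classes in class_fractions: {bad}")
        fr = self.class_fractions
        lesion = sum(v for k, v in fr.items() if k != "Norm")
        if lesion > 1.0 + 1e-9 or any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be in [0,1] and sum to <= 1")
        if "Norm" in fr and abs(fr["Norm"] + lesion - 1.0) > 1e-6:
            raise ValueError("explicit Norm fraction must make fractions sum to 1")
        # the Emph HU rectangle is only 50 HU wide; keep 3-sigma margins inside
        if self.hu_noise_sd > 7.0:
            raise ValueError("hu_noise_sd > 7 HU leaves no admissible Emph HU band")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PhantomSpec":
        d = json.loads(s)
        for key in ("grid_shape", "spacing_mm", "lung_axes_frac", "focus_center_frac"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort with planted progression labels."""

    n_subjects: int = 100
    gold_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "GOLD0": 0.43, "PRISm": 0.12, "GOLD1": 0.08,
            "GOLD2": 0.19, "GOLD3": 0.12, "GOLD4": 0.06,
        }
    )
    effect_size: float = 1.0
    fast_fraction: float = 0.34
    grid_shape: tuple[int, int, int] = (45, 45, 45)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")
        if abs(sum(self.gold_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("gold_distribution probabilities must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "CohortSpec":
        d = json.loads(s)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _lung_geometry(spec: PhantomSpec):
    shape = np.array(spec.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = shape * np.asarray(spec.lung_axes_frac)
    return center, semi


def focus_mask(spec: PhantomSpec) -> np.ndarray:
    """Lesion-focus region (intersected with the lung) of a phantom spec."""
    center, semi = _lung_geometry(spec)
    lung = _ellipsoid_mask(spec.grid_shape, center, semi)
    fcenter = center + np.asarray(spec.focus_center_frac) * semi
    fsemi = semi * spec.focus_radius_frac
    return _ellipsoid_mask(spec.grid_shape, fcenter, fsemi) & lung


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _paint_pocket(labels, lung, code, center, offsets):
    """Assign a spherical pocket on still-Norm lung voxels; returns #new."""
    shape = labels.shape
    pts = np.rint(center).astype(int) + offsets
    ok = np.all((pts >= 0) & (pts < shape), axis=1)
    pts = pts[ok]
    idx = tuple(pts.T)
    paint = lung[idx] & (labels[idx] == CLASS_CODES["Norm"])
    sub = tuple(p[paint] for p in idx)
    labels[sub] = code
    return int(paint.sum())


def _cluster_radius(n_pockets: float, pocket_vol: float, coalescence: float) -> float:
    # target fill fraction of the cluster ball rises with coalescence, capped
    # in the tunnelled-mesh regime (~0.45): beyond that the overlapping
    # spheres saturate into a solid blob and chi returns to +1
    phi = 0.08 + 0.37 * coalescence
    vol = max(n_pockets, 1.0) * pocket_vol / phi
    return float((vol * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _uniform_in_mask(rng, mask_pts):
    return mask_pts[rng.integers(len(mask_pts))]


def _place_fsad_exact(labels, lung, spec: PhantomSpec, rng) -> None:
    k = int(spec.n_fsad_pockets)
    r = spec.pocket_radius_vox
    offsets = _ball_offsets(r)
    fmask = focus_mask(spec)
    # candidate centres keep the whole pocket inside the volume
    interior = np.argwhere(fmask)
    interior = interior[
        np.all((interior - r - 1 >= 0)
               & (interior + r + 1 < np.array(labels.shape)), axis=1)
    ]
    if len(interior) == 0:
        raise ValueError("focus region too small for the pocket radius")
    if spec.coalescence == 0.0:
        centers: list[np.ndarray] = []
        min_d2 = (2 * r + 3) ** 2
        for _ in range(20000):
            if len(centers) == k:
                break
            cand = _uniform_in_mask(rng, interior)
            if all(np.sum((cand - c) ** 2) >= min_d2 for c in centers):
                centers.append(cand)
        if len(centers) < k:
            raise ValueError("could not place disjoint fSAD pockets in the lung")
    else:
        ccenter = _uniform_in_mask(rng, interior)
        rad = _cluster_radius(k, len(offsets), spec.coalescence)
        centers = []
        lo = np.zeros(3)
        hi = np.array(labels.shape) - 1.0
        for _ in range(k):
            d = rng.normal(size=3)
            d *= rad * rng.random() ** (1 / 3) / np.linalg.norm(d)
            centers.append(np.clip(ccenter + d, lo, hi))
    for c in centers:
        _paint_pocket(labels, lung, CLASS_CODES["fSAD"], c, offsets)


def _place_fraction(labels, lung, code, target_count, radius, spec, rng,
                    coalescence=0.0, restrict_focus=True) -> None:
    if target_count <= 0:
        return
    offsets = _ball_offsets(radius)
    region = focus_mask(spec) if restrict_focus else lung
    pts = np.argwhere(region)
    if len(pts) == 0:
        raise ValueError("empty placement region")
    if target_count > len(pts):
        raise ValueError(
            f"class fractions infeasible for geometry: need {target_count} voxels "
            f"in a region of {len(pts)}"
        )
    k0 = target_count / len(offsets)
    ccenter = _uniform_in_mask(rng, pts)
    rad = _cluster_radius(max(coalescence * k0, 1.0), len(offsets),
                          max(coalescence, 0.05))
    lo = np.zeros(3)
    hi = np.array(labels.shape) - 1.0
    placed = 0
    max_iter = int(6 * k0) + 300
    for _ in range(max_iter):
        if placed >= target_count - len(offsets) / 2:
            return
        if rng.random() < coalescence:
            d = rng.normal(size=3)
            d *= rad * rng.random() ** (1 / 3) / np.linalg.norm(d)
            center = np.clip(ccenter + d, lo, hi)
        else:
            center = _uniform_in_mask(rng, pts)
        placed += _paint_pocket(labels, lung, code, center, offsets)
    raise ValueError("class fractions infeasible for geometry")


def _sample_hu(labels, lung, noise_sd, rng):
    insp = np.zeros(labels.shape)
    exp = np.zeros(labels.shape)
    margin = 0.5 + 3.0 * noise_sd
    for cls, ((ilo, ihi), (elo, ehi)) in _HU_RECTS.items():
        sel = lung & (labels == CLASS_CODES[cls])
        n = int(sel.sum())
        if n == 0:
            continue
        insp[sel] = rng.uniform(ilo + margin, ihi - margin, n)
        exp[sel] = rng.uniform(elo + margin, ehi - margin, n)
    if noise_sd > 0:
        insp[lung] += rng.normal(0.0, noise_sd, int(lung.sum()))
        exp[lung] += rng.normal(0.0, noise_sd, int(lung.sum()))
        np.clip(insp, -999.9, -250.1, out=insp, where=lung)
        np.clip(exp, -999.9, -250.1, out=exp, where=lung)
    return insp, exp


def generate_phantom(spec: PhantomSpec) -> tuple[PairedCT, PRMMap]:
    """Generate a paired-CT phantom and its ground-truth PRM label map.

    All lung voxels start as Norm; Emph, fSAD and PD lesions are painted in
    that order (later pockets never overwrite earlier lesions).  At
    ``hu_noise_sd = 0`` every lung voxel's HU pair lies strictly inside its
    class's threshold rectangle, so PRM classification recovers the planted
    labels exactly.
    """
    rng = np.random.default_rng(spec.seed)
    center, semi = _lung_geometry(spec)
    lung = _ellipsoid_mask(spec.grid_shape, center, semi)
    lung_count = int(lung.sum())

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[lung] = CLASS_CODES["Norm"]

    fr = spec.class_fractions
    emph_target = int(round(fr.get("Emph", 0.0) * lung_count))
    _place_fraction(labels, lung, CLASS_CODES["Emph"], emph_target,
                    max(2, spec.pocket_radius_vox - 1), spec, rng)
    if spec.n_fsad_pockets is not None:
        _place_fsad_exact(labels, lung, spec, rng)
    else:
        fsad_target = int(round(fr.get("fSAD", 0.0) * lung_count))
        _place_fraction(labels, lung, CLASS_CODES["fSAD"], fsad_target,
                        spec.pocket_radius_vox, spec, rng,
                        coalescence=spec.coalescence)
    pd_target = int(round(fr.get("PD", 0.0) * lung_count))
    _place_fraction(labels, lung, CLASS_CODES["PD"], pd_target,
                    spec.pocket_radius_vox + 1, spec, rng, restrict_focus=False)

    insp, exp = _sample_hu(labels, lung, spec.hu_noise_sd, rng)
    ct = PairedCT(insp_hu=insp, exp_hu=exp, lung_mask=lung,
                  spacing_mm=spec.spacing_mm)
    truth = PRMMap(labels=labels, percent_volume={})
    truth.percent_volume = percent_volume(truth, lung)
    return ct, truth


def nested_lesion_phantom(
    grid_shape=(61, 61, 61),
    core_radius: int = 12,
    shell_radius: int = 20,
    seed: int = 0,
) -> tuple[PairedCT, PRMMap]:
    """Phantom with an emphysema core wrapped in an fSAD shell.

    Mirrors the spatial arrangement probed by line profiles: moving away
    from the core, V_Emph falls while V_fSAD rises and then falls again.
    The core is sized against the default 21-voxel window so that the
    windowed V_Emph exceeds 0.6 at the centre and drops below 0.2 near the
    lung edge.
    """
    spec = PhantomSpec(grid_shape=grid_shape, seed=seed)
    rng = np.random.default_rng(seed)
    center, semi = _lung_geometry(spec)
    lung = _ellipsoid_mask(grid_shape, center, semi)
    labels = np.zeros(grid_shape, dtype=np.uint8)
    labels[lung] = CLASS_CODES["Norm"]
    core = _ellipsoid_mask(grid_shape, center, (core_radius,) * 3)
    shell = _ellipsoid_mask(grid_shape, center, (shell_radius,) * 3) & ~core
    labels[lung & shell] = CLASS_CODES["fSAD"]
    labels[lung & core] = CLASS_CODES["Emph"]
    insp, exp = _sample_hu(labels, lung, 0.0, rng)
    ct = PairedCT(insp_hu=insp, exp_hu=exp, lung_mask=lung,
                  spacing_mm=spec.spacing_mm)
    truth = PRMMap(labels=labels, percent_volume={})
    truth.percent_volume = percent_volume(truth, lung)
    return ct, truth


def shape_phantoms() -> dict[str, tuple[np.ndarray, int]]:
    """Binary test volumes with known Euler characteristics.

    Returns a mapping ``name -> (volume, chi)`` covering the elementary
    topologies: a point (1), a solid cube (1), a ring (0), a hollow shell
    (a topological sphere, 2) and a disjoint pair (2, additivity).
    """
    single = np.zeros((3, 3, 3), dtype=bool)
    single[1, 1, 1] = True

    cube = np.ones((3, 3, 3), dtype=bool)

    ring = np.ones((3, 3, 1), dtype=bool)
    ring[1, 1, 0] = False

    shell = np.ones((3, 3, 3), dtype=bool)
    shell[1, 1, 1] = False

    pair = np.zeros((5, 3, 3), dtype=bool)
    pair[0, 1, 1] = True
    pair[4, 1, 1] = True

    return {
        "single_voxel": (single, 1),
        "solid_cube": (cube, 1),
        "ring": (ring, 0),
        "hollow_shell": (shell, 2),
        "disjoint_pair": (pair, 2),
    }


# Per-GOLD spirometry distributions (mean, sd) and admissible boxes used to
# emulate a smoking-cohort table: FEV1 % predicted, FEV1/FVC and FEF25-75.
_GOLD_SPIRO = {
    # class: (pct mean, pct sd, pct lo, pct hi, ratio mean, ratio sd,
    #         ratio lo, ratio hi, fef mean, fef sd)
    "GOLD0": (97.4, 11.4, 80.0, 140.0, 0.79, 0.05, 0.70, 0.95, 2.81, 1.00),
    "PRISm": (70.6, 7.9, 40.0, 79.5, 0.77, 0.05, 0.70, 0.95, 1.79, 0.66),
    "GOLD1": (90.8, 8.7, 80.0, 130.0, 0.65, 0.04, 0.45, 0.695, 1.31, 0.50),
    "GOLD2": (65.0, 8.5, 50.0, 79.5, 0.58, 0.08, 0.35, 0.695, 0.80, 0.35),
    "GOLD3": (40.2, 5.7, 30.0, 49.5, 0.44, 0.09, 0.25, 0.695, 0.39, 0.16),
    "GOLD4": (22.6, 4.8, 12.0, 29.5, 0.31, 0.07, 0.15, 0.695, 0.21, 0.08),
}
_GOLD_AGE = {"GOLD0": 56.7, "PRISm": 57.1, "GOLD1": 61.6,
             "GOLD2": 62.6, "GOLD3": 64.3, "GOLD4": 64.1}

# phantom-parameter base distributions (slow progressors); fast progressors
# are shifted by effect_size * sd on fSAD burden and coalescence.
_FSAD_FRAC = (0.08, 0.03, 0.01, 0.20)   # mean, sd, clip lo, clip hi
_COALESCENCE = (0.25, 0.10, 0.0, 0.90)
_EMPH_FRAC = (0.015, 0.008, 0.0, 0.05)
_PD_FRAC = (0.04, 0.02, 0.0, 0.10)
_FOCUS_RADIUS = 0.70


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[PhantomSpec]]:
    """Synthetic cohort table plus one phantom spec per subject.

    Fast progressors (exactly ``round(fast_fraction * n)`` of them) receive
    FEV1 trajectories with a 5-year slope <= -60 ml/yr; their phantom fSAD
    fraction and coalescence are shifted upward by ``effect_size`` pooled
    SDs relative to slow progressors.  All base parameters are drawn before
    the labels are applied, so ``effect_size = 0`` yields identical
    fast/slow parameter distributions by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    gold_classes = list(spec.gold_distribution)
    gold = rng.choice(gold_classes, size=n,
                      p=list(spec.gold_distribution.values()))

    n_fast = int(np.floor(spec.fast_fraction * n + 0.5))
    is_fast = np.zeros(n, dtype=bool)
    is_fast[rng.permutation(n)[:n_fast]] = True

    # base phantom parameters, label-independent
    def _draw(params):
        m, s, lo, hi = params
        return m, s, lo, hi, rng.normal(m, s, n)

    fm, fs, flo, fhi, fsad = _draw(_FSAD_FRAC)
    cm, cs, clo, chi_, coal = _draw(_COALESCENCE)
    _, _, elo, ehi, emph = _draw(_EMPH_FRAC)
    _, _, plo, phi, pdisease = _draw(_PD_FRAC)
    fsad = np.clip(fsad + spec.effect_size * fs * is_fast, flo, fhi)
    coal = np.clip(coal + spec.effect_size * cs * is_fast, clo, chi_)
    emph = np.clip(emph, elo, ehi)
    pdisease = np.clip(pdisease, plo, phi)
    focus_center = rng.uniform(-0.25, 0.25, size=(n, 3))

    rows = []
    phantoms: list[PhantomSpec] = []
    for i in range(n):
        g = gold[i]
        pm, ps, plo_, phi_, rm, rs, rlo, rhi, fefm, fefs = _GOLD_SPIRO[g]
        pct = float(np.clip(rng.normal(pm, ps), plo_, phi_))
        ratio = float(np.clip(rng.normal(rm, rs), rlo, rhi))
        fef = float(max(rng.normal(fefm, fefs), 0.05))
        sex = "M" if rng.random() < 0.55 else "F"
        pred_fev1 = 3.4 if sex == "M" else 2.6
        fev1 = pred_fev1 * pct / 100.0
        fvc = fev1 / ratio
        age = float(np.clip(rng.normal(_GOLD_AGE[g], 8.5), 40, 85))
        bmi = float(np.clip(rng.normal(28.5, 6.0), 15, 50))
        pack_years = float(np.clip(rng.normal(45.0, 25.0), 10, 150))
        race = "NHW" if rng.random() < 0.7 else "AA"
        vendor = str(rng.choice(["GE", "Siemens", "Philips"],
                                p=[0.5, 0.35, 0.15]))
        if is_fast[i]:
            max_drop = max(62.0, min(300.0, 100.0 * fev1))
            delta = float(rng.uniform(-max_drop, -61.0))
        else:
            delta = float(rng.uniform(-59.0, 100.0))
        fev1_y5 = fev1 + 5.0 * delta / 1000.0

        pspec = PhantomSpec(
            grid_shape=spec.grid_shape,
            class_fractions={
                "fSAD": float(fsad[i]),
                "Emph": float(emph[i]),
                "PD": float(pdisease[i]),
            },
            coalescence=float(coal[i]),
            focus_radius_frac=_FOCUS_RADIUS,
            focus_center_frac=tuple(focus_center[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        phantoms.append(pspec)
        rows.append({
            "case_id": f"S{i:05d}",
            "gold_class": g,
            "fev1_pct_pred": pct,
            "fev1_fvc_ratio": ratio,
            "fev1_l": fev1,
            "fvc_l": fvc,
            "fef2575_lps": fef,
            "age": age,
            "sex": sex,
            "race": race,
            "bmi": bmi,
            "pack_years": pack_years,
            "ct_vendor": vendor,
            "fev1_y5_l": fev1_y5,
            "delta_fev1_ml_yr": delta,
            "progressor": "fast" if is_fast[i] else "slow",
            "planted_fsad_fraction": float(fsad[i]),
            "planted_coalescence": float(coal[i]),
            "phantom_seed": pspec.seed,
        })
    return pd.DataFrame(rows), phantoms


def generate_regression_cohort(
    n: int,
    betas: dict[str, float],
    compulsory_effects: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort with a planted standardized linear model for an outcome.

    Candidate predictors are independent standard normals; the outcome is
    ``sum(beta_j * x_j) + covariate effects + noise`` with total variance 1,
    so the planted coefficients are the true standardized betas.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.normal(60, 8.5, n),
        "sex": rng.choice(["M", "F"], n),
        "race": rng.choice(["NHW", "AA"], n, p=[0.7, 0.3]),
        "bmi": rng.normal(28.5, 6.0, n),
        "pack_years": rng.normal(45, 25, n),
        "ct_vendor": rng.choice(["GE", "Siemens", "Philips"], n),
    })
    y = np.zeros(n)
    var = 0.0
    for name, b in betas.items():
        x = rng.normal(0, 1, n)
        df[name] = x
        y += b * x
        var += b * b
    eff = compulsory_effects or {}
    for name, b in eff.items():
        x = (df[name] - df[name].mean()) / df[name].std()
        y += b * x.to_numpy()
        var += b * b
    if var >= 1.0:
        raise ValueError("planted effects imply variance >= 1")
    y += rng.normal(0, np.sqrt(1.0 - var), n)
    df["outcome"] = y
    return df
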