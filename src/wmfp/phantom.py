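"""Seeded synthetic cohorts for the white-matter subtyping pipeline.

The phantom emulates the statistical structure the group decomposition
assumes: three smooth, spatially (almost) non-overlapping weight fields in
white matter, each carrying a distinct multi-parameter fingerprint, mixed
linearly into per-subject maps of the seven analysis parameters on a common
grid, with between-subject variability, planted age/gender effects, additive
map noise, and a configurable set of missing (subject, parameter) entries.

The per-voxel generative model for subject s, parameter p is::

    map(v) = baseline_p
             + sum_c w_c(v) * (F_cp + jitter_csp + cov_cp(s) - baseline_p)
             + a_p * G(v) * m_rim(v)
             + common_sp + cov_global_p(s) + noise

inside the brain (0 outside), where F is the subtype fingerprint matrix and
w_c are the component weight fields (1 inside each component's core).  The
``a_p G m_rim`` term is a shared anatomical texture: one smooth random field
per cohort, identical across subjects, modulated by the grey-matter rim.  It
emulates the cortical/partial-volume heterogeneity that dominates the
spatial variance of real parameter maps (and keeps the group-level +/-4 SD
intensity clamp from truncating the subtype cores), while — being common to
all subjects — leaving the between-subject spread of ROI means untouched.
The published between-subject SD is treated as the *total* between-subject
spread: the random subject effect is scaled down so that covariate-driven
variance plus random variance reproduces it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dti import dwi_signal, tensor_from_eigen
from .fieldmaps import afi_signal_ratio
from .maps import ANALYSIS_PARAMS, ParameterMap, SubjectRecord
from .mt import mt_signal_ratio
from .pssfp import pssfp_signal_pair
from .relaxometry import mgre_signal, spgr_signal
from .sequences import (AFIParams, DTIParams, MGREParams, MTParams,
                        PSSFPParams, TwoPoolConstraints, VFAParams)
from .subtypes import SUBTYPES, baseline_vector, fingerprint_matrix, subject_sd_vector

logger = logging.getLogger(__name__)

COMPONENT_NAMES: tuple[str, ...] = ("track", "frontal", "central")

#: Default missing (subject index, parameter) entries: seven maps spread over
#: four subjects (susceptibility/R2*/MPF lost for two, R1 and R2 for one each).
DEFAULT_MISSING: tuple[tuple[int, str], ...] = (
    (0, "chi_m"), (0, "R2star"), (0, "MPF"),
    (1, "chi_m"), (1, "R2star"),
    (2, "R1"),
    (3, "R2"),
)


@dataclass
class BlobGeometry:
    """One smooth ellipsoidal component territory with a flat core."""

    name: str
    center_vox: tuple[float, float, float]  # offset from the grid center
    semi_axes_vox: tuple[float, float, float]
    core_fraction: float = 0.9


DEFAULT_GEOMETRIES: tuple[BlobGeometry, ...] = (
    BlobGeometry("track", (0.0, 0.0, -2.0), (8.0, 3.4, 2.7)),
    BlobGeometry("frontal", (0.0, 5.5, 1.0), (6.5, 3.4, 3.2)),
    BlobGeometry("central", (0.0, -1.5, 5.0), (6.5, 3.6, 3.0)),
)


@dataclass
class CovariateEffect:
    """A planted age slope / gender offset on one parameter.

    ``component`` is a component name, or None for a global (all-tissue)
    effect.  ``age_slope`` is units/year about the cohort mean age;
    ``gender_offset`` is the female-minus-male shift.
    """

    param: str
    component: str | None
    age_slope: float = 0.0
    gender_offset: float = 0.0


#: Planted effects: a global MPF decline with age; R1 declining with age in
#: the frontal territory but rising in the other two (a subtype-by-age
#: interaction); larger diffusivity (AD and RD) in women in the track
#: territory (a subtype-by-gender interaction on ADC).
DEFAULT_COVARIATE_EFFECTS: tuple[CovariateEffect, ...] = (
    CovariateEffect("MPF", None, age_slope=-0.03),
    CovariateEffect("R1", "frontal", age_slope=-0.003),
    CovariateEffect("R1", "track", age_slope=+0.002),
    CovariateEffect("R1", "central", age_slope=+0.002),
    CovariateEffect("AD", "track", gender_offset=+20.0),
    CovariateEffect("RD", "track", gender_offset=+20.0),
)


def _default_noise_sd() -> dict[str, float]:
    fp = fingerprint_matrix()
    spread = fp.max(axis=0) - fp.min(axis=0)
    return {p: 0.2 * s for p, s in zip(ANALYSIS_PARAMS, spread)}


@dataclass
class PhantomSpec:
    """Full description of a synthetic cohort."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_subjects: int = 20
    geometries: tuple[BlobGeometry, ...] = DEFAULT_GEOMETRIES
    fingerprints: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            name: dict(zip(ANALYSIS_PARAMS, row))
            for name, row in zip(COMPONENT_NAMES, fingerprint_matrix())
        })
    baseline: dict[str, float] = field(
        default_factory=lambda: dict(zip(ANALYSIS_PARAMS, baseline_vector())))
    subject_sd: dict[str, float] = field(
        default_factory=lambda: dict(zip(ANALYSIS_PARAMS, subject_sd_vector())))
    component_jitter_frac: float = 0.8
    covariate_effects: tuple[CovariateEffect, ...] = DEFAULT_COVARIATE_EFFECTS
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    anatomy_contrast_frac: float = 0.35
    anatomy_fwhm_mm: float = 10.0
    missing_entries: tuple[tuple[int, str], ...] = DEFAULT_MISSING
    age_range: tuple[float, float] = (20.0, 58.0)
    max_pair_overlap: float = 0.10
    max_pair_correlation: float = 0.2
    seed: int = 0

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.geometries)


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class PhantomGeometry:
    """Deterministic spatial layout: brain, tissue probabilities, components."""

    brain_mask: np.ndarray
    p_wm: np.ndarray
    p_gm: np.ndarray
    weights: np.ndarray  # (n_components, *grid)
    names: tuple[str, ...]


def build_component_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Build the ellipsoidal brain, WM/GM probability maps and weight fields.

    Rejects a spec whose component territories overlap by more than
    ``max_pair_overlap`` of either member or correlate above
    ``max_pair_correlation`` over in-brain voxels.
    """
    shape = spec.grid_shape
    center = (np.asarray(shape, float) - 1.0) / 2.0
    brain_semi = 0.44 * np.asarray(shape, float) * np.array([0.96, 1.03, 0.89])
    ijk = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                               indexing="ij"), axis=-1)
    rel = (ijk - center) / brain_semi
    rho = np.sqrt((rel ** 2).sum(axis=-1))
    brain = rho <= 1.0

    p_wm = 0.95 * _smoothstep((0.74 - rho) / 0.08) * brain
    p_gm = 0.90 * _smoothstep((rho - 0.66) / 0.08) * brain

    weights = []
    for g in spec.geometries:
        c = center + np.asarray(g.center_vox, float)
        d = np.sqrt((((ijk - c) / np.asarray(g.semi_axes_vox, float)) ** 2).sum(axis=-1))
        w = np.where(d <= g.core_fraction, 1.0,
                     _smoothstep((1.0 - d) / (1.0 - g.core_fraction)))
        weights.append(w * brain)
    weights = np.stack(weights)

    names = spec.component_names
    for i in range(len(weights)):
        for j in range(i + 1, len(weights)):
            si = weights[i] >= 0.5
            sj = weights[j] >= 0.5
            inter = np.sum(si & sj)
            if inter > spec.max_pair_overlap * min(si.sum(), sj.sum()):
                raise ValueError(
                    f"components {names[i]!r} and {names[j]!r} overlap by more "
                    f"than {spec.max_pair_overlap:.0%} of either territory")
            wi, wj = weights[i][brain], weights[j][brain]
            r = np.corrcoef(wi, wj)[0, 1]
            if r > spec.max_pair_correlation:
                raise ValueError(
                    f"components {names[i]!r} and {names[j]!r} spatially "
                    f"correlate at r={r:.2f} > {spec.max_pair_correlation}")
    return PhantomGeometry(brain, p_wm, p_gm, weights, names)


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-simulation."""

    geometry: PhantomGeometry
    spec: PhantomSpec
    covariates: pd.DataFrame  # subject_id, age, gender
    component_values: np.ndarray  # (n_components, n_subjects, n_params): noiseless
    subject_offsets: np.ndarray  # (n_subjects, n_params): common + global effects
    anatomy_field: np.ndarray | None = None  # rim-modulated shared texture
    anatomy_amplitude: np.ndarray | None = None  # per-parameter amplitude a_p
    tracts: dict[str, np.ndarray] | None = None

    def true_map(self, subject_idx: int, param: str) -> np.ndarray:
        """Reconstruct a subject's noiseless parameter map."""
        p = ANALYSIS_PARAMS.index(param)
        base = self.spec.baseline[param]
        out = np.full(self.geometry.brain_mask.shape, 0.0)
        inside = np.full(self.geometry.brain_mask.shape, base, dtype=float)
        for c in range(self.geometry.weights.shape[0]):
            inside += self.geometry.weights[c] * (
                self.component_values[c, subject_idx, p] - base)
        if self.anatomy_field is not None:
            inside += self.anatomy_amplitude[p] * self.anatomy_field
        inside += self.subject_offsets[subject_idx, p]
        out[self.geometry.brain_mask] = inside[self.geometry.brain_mask]
        return out

    def smoothed_weights(self, fwhm_mm: float, mask: np.ndarray | None = None
                         ) -> np.ndarray:
        """Component weight fields at the pipeline's smoothing resolution.

        Recovery of sources from smoothed maps is scored against the truth
        carried to the same resolution; returns (n_components, n_mask_voxels)
        when ``mask`` is given, else smoothed volumes.
        """
        from scipy.ndimage import gaussian_filter
        sig = [fwhm_mm / 2.3548 / v for v in self.spec.voxel_size_mm]
        sm = np.stack([gaussian_filter(w, sig, mode="nearest", truncate=8.0)
                       for w in self.geometry.weights])
        if mask is not None:
            return sm[:, np.asarray(mask, bool)]
        return sm

    def atlas(self) -> "SubtypeAtlas":
        """A SubtypeAtlas whose ROIs are the planted pure cores.

        Lets extraction and statistics run against the planted ROIs without a
        decomposition — the oracle path for scoring the statistics machinery.
        Core indicators (w >= 0.999) are z-scored so the usual extraction
        threshold selects exactly the cores.
        """
        from .decompose import SubtypeAtlas
        brain = self.geometry.brain_mask
        z = []
        for w in self.geometry.weights:
            v = (w[brain] >= 0.999).astype(float)
            z.append((v - v.mean()) / max(v.std(), 1e-12))
        return SubtypeAtlas(np.vstack(z), brain, list(self.geometry.names), {})

    def core_mask(self, component: int | str) -> np.ndarray:
        if isinstance(component, str):
            component = list(self.geometry.names).index(component)
        return self.geometry.weights[component] >= 0.999


def generate_phantom_cohort(spec: PhantomSpec | None = None
                            ) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate a seeded cohort of subject records plus its ground truth."""
    spec = spec or PhantomSpec()
    geom = build_component_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    n_sub = spec.n_subjects
    n_par = len(ANALYSIS_PARAMS)
    n_comp = len(spec.geometries)
    names = spec.component_names

    ages = rng.uniform(*spec.age_range, size=n_sub)
    genders = np.array(["F", "M"] * ((n_sub + 1) // 2))[:n_sub]
    rng.shuffle(genders)
    age_c = ages - ages.mean()
    gsign = np.where(genders == "F", 0.5, -0.5)

    sd = np.array([spec.subject_sd[p] for p in ANALYSIS_PARAMS])
    # covariate-driven between-subject variance per (component, parameter)
    slope = np.zeros((n_comp, n_par))
    goffs = np.zeros((n_comp, n_par))
    gslope = np.zeros(n_par)
    goffs_g = np.zeros(n_par)
    for eff in spec.covariate_effects:
        p = ANALYSIS_PARAMS.index(eff.param)
        if eff.component is None:
            gslope[p] += eff.age_slope
            goffs_g[p] += eff.gender_offset
        else:
            c = names.index(eff.component)
            slope[c, p] += eff.age_slope
            goffs[c, p] += eff.gender_offset
    # Calibrate so each component's total between-subject variance equals the
    # published SD^2: a shared subject effect (fraction sqrt(1 - f^2) of the
    # SD, f = component_jitter_frac), plus component-specific jitter absorbing
    # the remainder after the covariate-driven variance is accounted for.
    var_age = np.var(age_c)
    var_cov = ((slope + gslope) ** 2 * var_age
               + (goffs + goffs_g) ** 2 * 0.25)  # per (component, param)
    frac = np.clip(spec.component_jitter_frac, 0.0, 1.0)
    common_sd = np.sqrt(1.0 - frac ** 2) * sd
    jit_sd = np.sqrt(np.maximum(sd[None, :] ** 2 - common_sd[None, :] ** 2
                                - var_cov, (0.25 * sd[None, :]) ** 2))

    common = rng.normal(0.0, 1.0, size=(n_sub, n_par)) * common_sd
    jitter = rng.normal(0.0, 1.0, size=(n_comp, n_sub, n_par)) * jit_sd[:, None, :]

    fp = np.array([[spec.fingerprints[name][p] for p in ANALYSIS_PARAMS]
                   for name in names])
    comp_vals = (fp[:, None, :] + jitter
                 + slope[:, None, :] * age_c[None, :, None]
                 + goffs[:, None, :] * gsign[None, :, None])
    subj_off = (common + gslope[None, :] * age_c[:, None]
                + goffs_g[None, :] * gsign[:, None])

    base = np.array([spec.baseline[p] for p in ANALYSIS_PARAMS])

    # shared anatomical texture: one smooth unit-SD field, rim-modulated
    from scipy.ndimage import gaussian_filter
    sig_vox = [spec.anatomy_fwhm_mm / 2.3548 / v for v in spec.voxel_size_mm]
    raw = gaussian_filter(rng.normal(size=spec.grid_shape), sig_vox,
                          mode="nearest", truncate=4.0)
    raw = raw / max(raw[geom.brain_mask].std(), 1e-12)
    anat_field = raw * (geom.p_gm / max(geom.p_gm.max(), 1e-12))
    anat_amp = spec.anatomy_contrast_frac * np.abs(fp.mean(axis=0) - base)

    cov = pd.DataFrame({"subject_id": [f"sub-{i:02d}" for i in range(n_sub)],
                        "age": ages, "gender": genders})
    truth = GroundTruth(geom, spec, cov, comp_vals, subj_off,
                        anatomy_field=anat_field, anatomy_amplitude=anat_amp)
    truth.tracts = make_tract_fixtures(spec)

    noise_sd = np.array([spec.noise_sd[p] for p in ANALYSIS_PARAMS])
    brain = geom.brain_mask

    records: list[SubjectRecord] = []
    for s in range(n_sub):
        rec = SubjectRecord(
            subject_id=cov.subject_id[s],
            p_wm=ParameterMap(geom.p_wm, "pWM", cov.subject_id[s], spec.voxel_size_mm),
            p_gm=ParameterMap(geom.p_gm, "pGM", cov.subject_id[s], spec.voxel_size_mm),
            age=float(ages[s]), gender=str(genders[s]))
        for p_i, p in enumerate(ANALYSIS_PARAMS):
            inside = np.full(spec.grid_shape, base[p_i])
            for c in range(n_comp):
                inside = inside + geom.weights[c] * (comp_vals[c, s, p_i] - base[p_i])
            inside = inside + anat_amp[p_i] * anat_field + subj_off[s, p_i]
            if noise_sd[p_i] > 0:
                inside = inside + rng.normal(0.0, noise_sd[p_i], size=spec.grid_shape)
            data = np.where(brain, inside, 0.0)
            rec.maps[p] = ParameterMap(data, p, rec.subject_id, spec.voxel_size_mm)
        records.append(rec)

    records = inject_missing_entries(records, spec.missing_entries)
    return records, truth


def inject_missing_entries(records: list[SubjectRecord],
                           entries: tuple[tuple[int, str], ...] | list
                           ) -> list[SubjectRecord]:
    """Remove the designated (subject index, parameter) maps in place."""
    for s_idx, param in entries:
        if not (0 <= s_idx < len(records)):
            raise KeyError(f"missing entry references unknown subject {s_idx}")
        if param not in records[s_idx].maps:
            raise KeyError(
                f"missing entry ({s_idx}, {param!r}) references an absent map")
        del records[s_idx].maps[param]
    for rec in records:
        if not rec.usable_for_decomposition:
            logger.warning("subject %s has no analysis maps left; flagged "
                           "unusable for decomposition", rec.subject_id)
    return records


def inject_subject_artifact(records: list[SubjectRecord], subject_idx: int,
                            center_vox: tuple[float, float, float] = (-6.0, -5.0, 0.0),
                            radius_vox: float = 3.0,
                            amplitude_frac: float = 3.0) -> list[SubjectRecord]:
    """Add a subject-specific blob to every map of one subject.

    Emulates a single-subject artifact (motion, lesion): a source shared
    across that subject's parameters but absent in everyone else, which the
    between-parameter / between-subject loading-ratio criterion should
    reject.  Amplitude is ``amplitude_frac`` times each parameter's
    between-subject SD, applied inside a spherical bump.
    """
    rec = records[subject_idx]
    some = next(iter(rec.maps.values()))
    shape = some.data.shape
    center = (np.asarray(shape, float) - 1.0) / 2.0 + np.asarray(center_vox, float)
    ijk = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                               indexing="ij"), axis=-1)
    d = np.sqrt(((ijk - center) ** 2).sum(axis=-1)) / radius_vox
    bump = np.where(d <= 1.0, _smoothstep(1.0 - d), 0.0)
    sd = dict(zip(ANALYSIS_PARAMS, subject_sd_vector()))
    for p, m in rec.maps.items():
        if p in sd:
            inside = m.data != 0
            rec.maps[p] = m.with_data(m.data + amplitude_frac * sd[p] * bump * inside)
    return records


def make_tract_fixtures(spec: PhantomSpec | None = None) -> dict[str, np.ndarray]:
    """Synthetic tube-shaped tract label volumes.

    ``crossing`` runs vertically through the central and track territories
    (a fasciculus traversing two subtypes); ``confined`` lies entirely inside
    the track territory.
    """
    spec = spec or PhantomSpec()
    shape = spec.grid_shape
    center = (np.asarray(shape, float) - 1.0) / 2.0
    ijk = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                               indexing="ij"), axis=-1)

    # vertical tube at (x, y) = center + (0, -1), z spanning both territories
    axis_xy = center[:2] + np.array([0.0, -1.0])
    r_xy = np.sqrt(((ijk[..., :2] - axis_xy) ** 2).sum(axis=-1))
    z = ijk[..., 2] - center[2]
    crossing = (r_xy <= 1.6) & (z >= -3.0) & (z <= 7.0)

    # horizontal tube along x inside the track core
    axis_yz = center[1:] + np.array([0.0, -2.0])
    r_yz = np.sqrt(((ijk[..., 1:] - axis_yz) ** 2).sum(axis=-1))
    x = ijk[..., 0] - center[0]
    confined = (r_yz <= 1.2) & (np.abs(x) <= 3.5)

    return {"crossing": crossing, "confined": confined}


# ---------------------------------------------------------------------------
# raw-signal simulation


@dataclass
class SequenceSet:
    """The forward-model descriptors used to emit raw volumes."""

    mgre: MGREParams = field(default_factory=MGREParams)
    vfa: VFAParams = field(default_factory=VFAParams)
    afi: AFIParams = field(default_factory=AFIParams)
    mt: MTParams = field(default_factory=MTParams)
    pssfp: PSSFPParams = field(default_factory=PSSFPParams)
    dti: DTIParams = field(default_factory=DTIParams)
    constraints: TwoPoolConstraints = field(default_factory=TwoPoolConstraints)


def simulate_raw_signals(record: SubjectRecord, sequences: SequenceSet | None = None,
                         b1_field: np.ndarray | float = 1.0,
                         b0_field_hz: np.ndarray | float = 0.0,
                         s0: float = 100.0) -> dict[str, np.ndarray]:
    """Emit raw sequence volumes from a subject's true parameter maps.

    Each sequence is generated through the same forward model the fitters
    invert; a sequence whose prerequisite map is missing is skipped with a
    logged warning.  Brain-exterior voxels (value 0 in the parameter maps)
    produce zero signal.
    """
    seq = sequences or SequenceSet()
    out: dict[str, np.ndarray] = {}
    some = next(iter(record.maps.values()))
    shape = some.data.shape
    brain = np.zeros(shape, bool)
    for m in record.maps.values():
        brain |= m.data != 0
    b1 = np.broadcast_to(np.asarray(b1_field, float), shape)
    b0 = np.broadcast_to(np.asarray(b0_field_hz, float), shape)

    def _skip(name: str, needs: str) -> None:
        logger.warning("subject %s: cannot simulate %s (missing %s map)",
                       record.subject_id, name, needs)

    if "R2star" in record.maps:
        out["mgre"] = np.where(brain[..., None],
                               mgre_signal(np.full(shape, s0),
                                           record.maps["R2star"].data, seq.mgre), 0.0)
    else:
        _skip("MGRE", "R2star")

    if "R1" in record.maps:
        r1 = record.maps["R1"].data
        pair = []
        for fa in seq.vfa.flip_angles_deg:
            with np.errstate(invalid="ignore", divide="ignore"):
                sig = spgr_signal(s0, np.where(brain, r1, 1.0), fa * b1, seq.vfa.tr_ms)
            pair.append(np.where(brain, sig, 0.0))
        out["vfa"] = np.stack(pair, axis=-1)
    else:
        _skip("VFA", "R1")

    ratio = afi_signal_ratio(b1, seq.afi)
    out["afi"] = np.stack([np.where(brain, s0, 0.0),
                           np.where(brain, s0 * ratio, 0.0)], axis=-1)

    te1, te2 = seq.mt.te_pair_ms
    dphi = 2.0 * np.pi * b0 * (te2 - te1) / 1000.0
    out["mt_phase"] = np.stack([np.zeros(shape), np.where(brain, dphi, 0.0)], axis=-1)

    if "MPF" in record.maps and "R1" in record.maps:
        f = record.maps["MPF"].data / 100.0
        r1 = record.maps["R1"].data
        ratio_mt = mt_signal_ratio(np.where(brain, f, 0.0),
                                   np.where(brain, r1, 1.0),
                                   seq.mt, seq.constraints, b0, b1)
        out["mt"] = np.stack([np.where(brain, s0 * ratio_mt, 0.0),
                              np.where(brain, s0, 0.0)], axis=-1)
    else:
        _skip("MT", "MPF and R1")

    if "R2" in record.maps:
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = np.where(record.maps["R2"].data > 0,
                          1.0 / record.maps["R2"].data, np.nan)
        sa, sb = pssfp_signal_pair(np.where(brain, t2, 0.05), seq.pssfp, b1, s0)
        out["pssfp"] = np.stack([np.where(brain, sa, 0.0),
                                 np.where(brain, sb, 0.0)], axis=-1)
    else:
        _skip("pSSFP", "R2")

    if "AD" in record.maps and "RD" in record.maps:
        ad = record.maps["AD"].data
        rd = record.maps["RD"].data
        vols = np.zeros(shape + (seq.dti.bvals.size,))
        idx = np.flatnonzero(brain.ravel())
        if idx.size:
            lam = np.stack([ad.ravel()[idx], rd.ravel()[idx], rd.ravel()[idx]], axis=1)
            b = seq.dti.bvals
            g = seq.dti.bvecs
            # tensor aligned with the x axis everywhere
            bq = np.outer(lam[:, 0] / 1e6, b * g[:, 0] ** 2) + \
                 np.outer(lam[:, 1] / 1e6, b * (g[:, 1] ** 2 + g[:, 2] ** 2))
            flat = vols.reshape(-1, b.size)
            flat[idx] = s0 * np.exp(-bq)
            vols = flat.reshape(shape + (b.size,))
        out["dwi"] = vols
    else:
        _skip("DTI", "AD and RD")
    return out
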