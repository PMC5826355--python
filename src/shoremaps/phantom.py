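"""Synthetic longitudinal cohort generator.

The generator emulates the statistical structure of a two-group
longitudinal diffusion-MRI study: ten healthy controls scanned twice and
ten stroke patients scanned at three time points, with microstructural
modulations confined to the hemisphere contralateral to the lesion.  It
provides three layers:

* voxel level — multi-compartment Gaussian (tensor) signals on a DSI
  scheme, with Rician magnitude noise calibrated to a target b0 SNR;
* geometry — a toy brain: 36 bilateral gray-matter parcels (eight of
  which are the motor regions M1, SMA, SC, PM, Thl, Cau, Put, GPi), a
  midline corpus-callosum block, and polyline fiber bundles wiring the
  transcallosal (CC), cortical (CORT) and subcortical (SUBCORT) motor
  networks;
* cohort level — either full 4-D volumes per subject and session, or a
  measure-level table that draws per-connection / per-region index values
  directly from the declared variance components (between-subject CV,
  within-subject CV, per-session patient effect profile).

The measure-level route exists because test-retest and group statistics
need cohort sizes that would be wasteful to push through voxel-wise
fitting; it draws from the same latent subject effects as the image
route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qspace import AcquisitionScheme

__all__ = [
    "CompartmentSpec",
    "CohortSpec",
    "ToyGeometry",
    "simulate_voxel_signal",
    "add_rician_noise",
    "estimate_snr",
    "build_toy_geometry",
    "simulate_measure_table",
    "build_cohort",
    "INDEX_NAMES",
    "WM_EIGENVALUES",
    "GM_EIGENVALUES",
]

INDEX_NAMES = ("gfa", "pa", "rtap", "rtpp", "msd", "fa", "md")

#: Tract-averaged white-matter tensor (mm^2/s).  Bundle means mix the
#: coherent fiber core with dispersion and partial volume, so the radial
#: eigenvalue is well above the single-axon value; with the default
#: b_max = 8,000 s/mm^2 scheme the perpendicular signal decay
#: (b_max * lperp ~ 5) is essentially complete within the sampled range.
WM_EIGENVALUES = (1.55e-3, 0.65e-3, 0.65e-3)

#: Gray matter: weakly anisotropic, MD ~ 0.87e-3 mm^2/s.
GM_EIGENVALUES = (1.1e-3, 0.75e-3, 0.75e-3)

#: Typical magnitudes of the seven indices for contralateral tract/ROI
#: means (consistent with the WM tensor above at tau = 0.0538 s); the
#: measure-level simulator scales its variance components off these.
INDEX_BASELINES = {
    "gfa": 0.55,
    "pa": 0.60,
    "rtap": 2.3e3,  # mm^-2
    "rtpp": 30.0,  # mm^-1
    "msd": 3.1e-4,  # mm^2
    "fa": 0.50,
    "md": 0.9e-3,  # mm^2/s
}

#: Per-session multiplicative patient effects (tp1, tp2, tp3) relative to
#: the control level: anisotropy and the zero-displacement probabilities
#: elevated just after the event and renormalizing, diffusivity rising at
#: the later time points.
DEFAULT_EFFECT_PROFILE = {
    "gfa": (1.10, 1.00, 0.98),
    "pa": (1.10, 1.00, 0.98),
    "fa": (1.10, 1.00, 0.98),
    "rtap": (1.08, 1.00, 0.99),
    "rtpp": (1.06, 1.00, 1.00),
    "msd": (1.00, 1.08, 1.10),
    "md": (1.00, 1.08, 1.10),
}

MOTOR_CORTICAL = ("M1", "SMA", "SC", "PM")
MOTOR_SUBCORTICAL = ("Thl", "Cau", "Put", "GPi")
CC_REGION = "CC"

#: GM regions receiving the patient effect profile (the contralateral
#: modulations are regional, not global, which is what makes the
#: Group x TP x Region interaction testable): the motor regions plus a
#: handful of the filler parcels.
DEFAULT_AFFECTED_ROIS = MOTOR_CORTICAL + MOTOR_SUBCORTICAL + (
    "G09",
    "G10",
    "G11",
    "G12",
)


# --------------------------------------------------------------------------
# voxel-level signals

@dataclass(frozen=True)
class CompartmentSpec:
    """One Gaussian tissue compartment: an axially oriented tensor with a
    volume fraction."""

    eigenvalues: tuple[float, float, float]  # (l_par, l_perp1, l_perp2) mm^2/s
    orientation: tuple[float, float, float]  # unit vector for l_par
    volume_fraction: float

    def tensor(self) -> np.ndarray:
        e1 = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(e1)
        if norm == 0:
            raise ValueError("orientation must be nonzero")
        e1 = e1 / norm
        helper = (
            np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        )
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        basis = np.column_stack([e1, e2, e3])
        return basis @ np.diag(self.eigenvalues) @ basis.T


def simulate_voxel_signal(
    compartments: list[CompartmentSpec], scheme: AcquisitionScheme
) -> np.ndarray:
    """Noise-free attenuation E(q) of a Gaussian mixture,
    ``E = sum_c f_c exp(-b u^T D_c u)`` with ``E(0) = 1``."""
    if not compartments:
        raise ValueError("need at least one compartment")
    for c in compartments:
        if any(ev <= 0 for ev in c.eigenvalues):
            raise ValueError("compartment eigenvalues must be positive")
    fsum = sum(c.volume_fraction for c in compartments)
    if abs(fsum - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {fsum}, expected 1")
    u = scheme.directions
    b = scheme.bvals
    out = np.zeros(scheme.n_samples)
    for c in compartments:
        D = c.tensor()
        out += c.volume_fraction * np.exp(-b * np.einsum("ij,jk,ik->i", u, D, u))
    return out


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Magnitude-MRI noise: ``sqrt((s + n1)^2 + n2^2)`` with iid Gaussian
    ``n1, n2 ~ N(0, sigma^2)``.  Reproducible given the rng/seed."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be nonnegative")
    if sigma == 0:
        return signal.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


#: SD of a Rayleigh variate is sigma * sqrt(2 - pi/2); inverting it turns a
#: background (pure-noise) SD into the underlying Gaussian sigma.
_RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


def estimate_snr(
    volume: np.ndarray,
    signal_roi: np.ndarray,
    background_roi: np.ndarray,
    b0_index: int = 0,
) -> float:
    """SNR = mean(b0 signal ROI) / sigma_gauss, with the Gaussian noise SD
    recovered from the Rayleigh-distributed background magnitude."""
    vol = np.asarray(volume)
    b0 = vol[..., b0_index] if vol.ndim == 4 else vol
    if not signal_roi.any() or not background_roi.any():
        raise ValueError("both ROIs must be nonempty")
    bg = b0[background_roi]
    sd = float(np.std(bg, ddof=1))
    if sd == 0:
        raise ValueError("background has zero variance (noiseless input)")
    sigma_gauss = sd / _RAYLEIGH_SD_FACTOR
    return float(np.mean(b0[signal_roi]) / sigma_gauss)


# --------------------------------------------------------------------------
# toy geometry

@dataclass
class ToyGeometry:
    """Toy parcellation, GM probability map and fiber bundles.

    Labels: region ``i`` (1-based) has left label ``i`` and right label
    ``100 + i``; the corpus callosum block carries label 99.  Streamlines
    are stored in voxel coordinates (0-based, corner origin).
    """

    shape: tuple[int, int, int]
    parcellation: np.ndarray  # int16 labels
    gm_probability: np.ndarray  # float32 in [0, 1]
    region_names: list[str]
    networks: dict[str, list[tuple[str, str]]]
    bundles: dict[tuple[str, str], list[np.ndarray]]  # (network, "A-B") -> streamlines
    cc_label: int = 99

    def labels_for(self, region: str) -> tuple[int, int]:
        if region == CC_REGION:
            return self.cc_label, self.cc_label
        i = self.region_names.index(region) + 1
        return i, 100 + i

    def connection_key(self, network: str, a: str, b: str) -> tuple[str, str]:
        return network, f"{a}-{b}"

    @property
    def connections(self) -> list[tuple[str, str]]:
        return sorted(self.bundles.keys())


def _default_networks() -> dict[str, list[tuple[str, str]]]:
    cc = [(CC_REGION, r) for r in MOTOR_CORTICAL + MOTOR_SUBCORTICAL]
    cort = [
        (a, b)
        for i, a in enumerate(MOTOR_CORTICAL)
        for b in MOTOR_CORTICAL[i + 1 :]
    ]
    subcort = [
        (a, b) for a in ("M1", "SMA", "PM") for b in MOTOR_SUBCORTICAL
    ]
    return {"CC": cc, "CORT": cort, "SUBCORT": subcort}


def _streamline(p0: np.ndarray, p1: np.ndarray, offset: np.ndarray, step: float = 0.4):
    """Polyline from p0 to p1 with a sine-tapered perpendicular offset, so
    the endpoints stay exactly at the parcel centers."""
    length = np.linalg.norm(p1 - p0)
    n_pts = max(int(np.ceil(length / step)) + 1, 5)
    t = np.linspace(0.0, 1.0, n_pts)
    base = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    return base + np.sin(np.pi * t)[:, None] * offset[None, :]


def build_toy_geometry(
    grid_shape: tuple[int, int, int] = (26, 16, 14),
    n_streamlines_per_bundle: int = 5,
    n_gm_regions: int = 36,
    block_size: int = 2,
) -> ToyGeometry:
    """Deterministic placement of labeled parcels and motor-network bundles.

    Gray-matter blocks are laid on a lattice of free slots per hemisphere
    (cortical motor regions lateral, subcortical nuclei medial, filler
    regions in the remaining slots); the right hemisphere mirrors the
    left.  Raises when the grid cannot host all parcels.
    """
    nx, ny, nz = grid_shape
    if n_gm_regions < len(MOTOR_CORTICAL) + len(MOTOR_SUBCORTICAL):
        raise ValueError("need at least the 8 motor regions")
    half = nx // 2
    bs = block_size
    gap = 1
    x_slots = list(range(1, half - bs, bs + gap))
    y_slots = list(range(1, ny - bs + 1, bs + gap))
    z_slots = list(range(1, nz - bs + 1, bs + gap))
    capacity = len(x_slots) * len(y_slots) * len(z_slots)
    if capacity < n_gm_regions or len(x_slots) < 2:
        raise ValueError(
            f"grid {grid_shape} too small for {n_gm_regions} regions "
            f"(capacity {capacity})"
        )

    region_names = list(MOTOR_CORTICAL + MOTOR_SUBCORTICAL) + [
        f"G{i:02d}" for i in range(9, n_gm_regions + 1)
    ]
    # cortical regions on the most lateral slab, subcortical on the most
    # medial, fillers in remaining slots (deterministic order)
    lateral, medial = x_slots[0], x_slots[-1]
    yz = [(y, z) for z in z_slots for y in y_slots]
    slot_of: dict[str, tuple[int, int, int]] = {}
    for i, name in enumerate(MOTOR_CORTICAL):
        slot_of[name] = (lateral, *yz[i])
    for i, name in enumerate(MOTOR_SUBCORTICAL):
        slot_of[name] = (medial, *yz[i])
    filler_slots = [
        (x, y, z)
        for x in x_slots
        for (y, z) in yz
        if (x, y, z) not in slot_of.values()
    ]
    for name, slot in zip(region_names[8:], filler_slots):
        slot_of[name] = slot

    parc = np.zeros(grid_shape, dtype=np.int16)
    gm_prob = np.zeros(grid_shape, dtype=np.float32)
    for i, name in enumerate(region_names):
        x, y, z = slot_of[name]
        label = i + 1
        parc[x : x + bs, y : y + bs, z : z + bs] = label
        parc[nx - x - bs : nx - x, y : y + bs, z : z + bs] = 100 + label
        gm_prob[x : x + bs, y : y + bs, z : z + bs] = 0.98
        gm_prob[nx - x - bs : nx - x, y : y + bs, z : z + bs] = 0.98

    # midline corpus callosum block
    cc_y0, cc_z0 = y_slots[0], z_slots[0]
    cx = half - 1
    parc[cx : cx + 2, cc_y0 : cc_y0 + bs, cc_z0 : cc_z0 + bs] = 99
    gm_prob[cx : cx + 2, cc_y0 : cc_y0 + bs, cc_z0 : cc_z0 + bs] = 0.2

    def center(region: str) -> np.ndarray:
        if region == CC_REGION:
            return np.array([cx + 1.0, cc_y0 + bs / 2.0, cc_z0 + bs / 2.0])
        x, y, z = slot_of[region]
        return np.array([x + bs / 2.0, y + bs / 2.0, z + bs / 2.0])

    networks = _default_networks()
    bundles: dict[tuple[str, str], list[np.ndarray]] = {}
    max_off = 0.3 * bs
    for net, pairs in networks.items():
        for a, b in pairs:
            p0, p1 = center(a), center(b)
            axis = p1 - p0
            axis = axis / np.linalg.norm(axis)
            helper = (
                np.array([0.0, 0.0, 1.0])
                if abs(axis[2]) < 0.9
                else np.array([0.0, 1.0, 0.0])
            )
            perp = np.cross(axis, helper)
            perp /= np.linalg.norm(perp)
            lines = []
            for k in range(n_streamlines_per_bundle):
                frac = (k - (n_streamlines_per_bundle - 1) / 2.0) / max(
                    n_streamlines_per_bundle - 1, 1
                )
                lines.append(_streamline(p0, p1, (2.0 * frac * max_off) * perp))
            bundles[(net, f"{a}-{b}")] = lines
    return ToyGeometry(
        shape=grid_shape,
        parcellation=parc,
        gm_probability=gm_prob,
        region_names=region_names,
        networks=networks,
        bundles=bundles,
    )


# --------------------------------------------------------------------------
# cohort specification and latent structure

@dataclass
class CohortSpec:
    """Study-design parameters of the emulated cohort."""

    n_controls: int = 10
    n_patients: int = 10
    sessions_controls: int = 2
    sessions_patients: int = 3
    snr_b0: float = 28.0
    intra_subject_cv: float = 0.03
    inter_subject_cv: float = 0.10
    effect_profile: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILE)
    )
    affected_rois: tuple[str, ...] = DEFAULT_AFFECTED_ROIS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intra_subject_cv < 0 or self.inter_subject_cv < 0:
            raise ValueError("CVs must be >= 0")
        for name, prof in self.effect_profile.items():
            if any(p <= 0 for p in prof):
                raise ValueError(f"effect profile for {name} must be positive")

    def effect(
        self, group: str, index: str, session: int, unit_type: str = "connection",
        unit_id: str = "",
    ) -> float:
        """Multiplicative modulation for session (1-based); controls 1.

        Connection units are all affected (the motor networks are the
        structures of interest); ROI effects are restricted to the
        designated ``affected_rois``."""
        if group != "patient":
            return 1.0
        if unit_type == "roi" and unit_id not in self.affected_rois:
            return 1.0
        prof = self.effect_profile.get(index)
        if prof is None:
            return 1.0
        return prof[session - 1]


def _subject_table(spec: CohortSpec) -> list[tuple[str, str, int]]:
    rows = []
    for i in range(spec.n_controls):
        rows.append((f"ctrl{i + 1:02d}", "control", spec.sessions_controls))
    for i in range(spec.n_patients):
        rows.append((f"pat{i + 1:02d}", "patient", spec.sessions_patients))
    return rows


def _covariates(
    spec: CohortSpec,
    latents: dict[tuple[str, str], float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical table with the declared monotone link: the motor NIHSS at
    tp3 increases with the patient's latent subcortical anisotropy level
    at tp1 (its GFA/RTPP subject effects), so that outcome regression on
    tp1 subcortical loop means is recoverable by construction."""
    rows = []
    for subject, group, n_sessions in _subject_table(spec):
        age = float(np.clip(rng.normal(60.3, 12.3), 30, 90))
        if group == "control":
            for s in range(1, n_sessions + 1):
                rows.append((subject, group, s, age, 0.0, 0))
            continue
        stroke_size = float(np.exp(rng.normal(np.log(20.0), 0.6)))
        z_gfa = latents[(subject, "gfa")]
        z_rtpp = latents[(subject, "rtpp")]
        # baseline severity tracks the same latent anisotropy level (a
        # sicker network at tp1 scores worse already at baseline), so the
        # clinical reference model retains moderate predictive power
        nihss1 = int(
            np.clip(
                round(4.0 + 0.05 * stroke_size + 10.0 * z_gfa + rng.normal(0, 1.1)),
                1,
                14,
            )
        )
        nihss3 = int(
            np.clip(round(4.0 + 22.0 * z_gfa + 13.0 * z_rtpp + rng.normal(0, 0.35)), 0, 15)
        )
        nihss = {1: nihss1, 2: int(np.clip(nihss1 - 1, 0, 15)), 3: nihss3}
        for s in range(1, n_sessions + 1):
            rows.append((subject, group, s, age, stroke_size, nihss[s]))
    return pd.DataFrame(
        rows, columns=["subject", "group", "session", "age", "stroke_size", "nihss"]
    )


def _subject_latents(
    spec: CohortSpec, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    """Per-(subject, index) standardized levels z with SD = inter CV."""
    latents = {}
    for subject, _, _ in _subject_table(spec):
        for index in INDEX_NAMES:
            latents[(subject, index)] = float(rng.normal(0.0, spec.inter_subject_cv))
    return latents


def _cohort_streams(spec: CohortSpec):
    """Independent reproducible RNG streams for latents, covariates and
    session noise — the measure-level and image-level generators share the
    latent and covariate draws for a given seed."""
    lat_ss, cov_ss, noise_ss = np.random.SeedSequence(spec.seed).spawn(3)
    return (
        np.random.default_rng(lat_ss),
        np.random.default_rng(cov_ss),
        noise_ss,
    )


def simulate_measure_table(
    spec: CohortSpec,
    geometry: ToyGeometry | None = None,
    contralateral_factors: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a long-format measure table directly from the variance model.

    Each record is ``baseline(index) * unit_factor * (1 + z_subject,index)
    * effect(group, index, session) * (1 + eps_session)`` with
    ``z ~ N(0, inter_cv)`` and ``eps ~ N(0, intra_cv)``.  Units are the
    connections of the three motor networks and the GM regions of the
    geometry.  Patient effects model the contralateral hemisphere, the one
    quantified downstream.  Returns ``(measures, covariates)``.
    """
    if geometry is None:
        geometry = build_toy_geometry()
    lat_rng, cov_rng, noise_ss = _cohort_streams(spec)
    latents = _subject_latents(spec, lat_rng)
    rng = np.random.default_rng(noise_ss)
    units: list[tuple[str, str]] = [
        ("connection", f"{net}:{conn}") for net, conn in geometry.connections
    ] + [("roi", name) for name in geometry.region_names]
    # deterministic mild spread of unit baselines (+-12%)
    unit_factor = {
        uid: 1.0 + 0.12 * np.sin(2.1 * k + 0.7)
        for k, (_, uid) in enumerate(units)
    }
    rows = []
    for subject, group, n_sessions in _subject_table(spec):
        for session in range(1, n_sessions + 1):
            for index in INDEX_NAMES:
                level = INDEX_BASELINES[index] * (1.0 + latents[(subject, index)])
                for unit_type, uid in units:
                    eff = spec.effect(group, index, session, unit_type, uid)
                    eps = rng.normal(0.0, spec.intra_subject_cv)
                    value = level * unit_factor[uid] * eff * (1.0 + eps)
                    rows.append(
                        (subject, group, session, unit_type, uid, index, value)
                    )
    measures = pd.DataFrame(
        rows,
        columns=["subject", "group", "session", "unit_type", "unit_id", "index", "value"],
    )
    covariates = _covariates(spec, latents, cov_rng)
    return measures, covariates


# --------------------------------------------------------------------------
# image-level cohort

def _bundle_voxel_directions(geometry: ToyGeometry) -> dict[tuple[int, int, int], list[np.ndarray]]:
    """Voxel -> list of distinct local fiber directions (crossing support)."""
    out: dict[tuple[int, int, int], list[np.ndarray]] = {}
    for lines in geometry.bundles.values():
        for line in lines:
            seg = np.diff(line, axis=0)
            for p, d in zip(line[:-1], seg):
                norm = np.linalg.norm(d)
                if norm == 0:
                    continue
                d = d / norm
                vox = tuple(int(np.floor(c)) for c in p)
                if any(c < 0 for c in vox) or any(
                    c >= s for c, s in zip(vox, geometry.shape)
                ):
                    continue
                dirs = out.setdefault(vox, [])
                if all(abs(float(d @ e)) < np.cos(np.radians(30.0)) for e in dirs):
                    if len(dirs) < 2:
                        dirs.append(d)
    return out


def tissue_mask(geometry: ToyGeometry) -> np.ndarray:
    """Voxels carrying spins: parcels, corpus callosum and bundle
    corridors.  The complement is pure-noise background (the ROI used for
    Rayleigh noise estimation)."""
    mask = geometry.parcellation != 0
    for vox in _bundle_voxel_directions(geometry):
        mask[vox] = True
    return mask


def _voxel_compartments(
    geometry: ToyGeometry,
) -> dict[tuple[int, int, int], list[CompartmentSpec]]:
    """Noise-free tissue model: WM tensors along bundle tangents (two
    compartments where bundles cross), CC along x, GM blocks with a
    deterministic per-region orientation."""
    comps: dict[tuple[int, int, int], list[CompartmentSpec]] = {}
    for vox, dirs in _bundle_voxel_directions(geometry).items():
        f = 1.0 / len(dirs)
        comps[vox] = [
            CompartmentSpec(WM_EIGENVALUES, tuple(d), f) for d in dirs
        ]
    parc = geometry.parcellation
    for vox in zip(*np.nonzero(parc)):
        label = int(parc[vox])
        if vox in comps:
            continue
        if label == geometry.cc_label:
            comps[vox] = [CompartmentSpec(WM_EIGENVALUES, (1.0, 0.0, 0.0), 1.0)]
        else:
            i = label - 100 if label > 100 else label
            ang = 0.9 * i
            ori = (np.cos(ang), np.sin(ang), 0.35)
            comps[vox] = [CompartmentSpec(GM_EIGENVALUES, ori, 1.0)]
    return comps


def _modulate(
    comp: CompartmentSpec, aniso: float, diffu: float
) -> CompartmentSpec:
    """Map index-level effects onto eigenvalues: the anisotropy factor
    stretches the parallel/radial ratio, the diffusivity factor scales the
    trace."""
    lp, l1, l2 = comp.eigenvalues
    return CompartmentSpec(
        (lp * diffu * aniso, l1 * diffu / aniso, l2 * diffu / aniso),
        comp.orientation,
        comp.volume_fraction,
    )


def build_cohort(
    spec: CohortSpec,
    geometry: ToyGeometry,
    scheme: AcquisitionScheme,
):
    """Generate the image-level cohort lazily.

    Yields ``(record, volume)`` per acquisition where ``record`` is a dict
    with subject, group and session and ``volume`` is the 4-D float32
    stack (S0 = 1 in tissue, empty background) with Rician noise at the
    target b0 SNR.  Patient modulations are applied in the left
    (contralateral-analog) hemisphere only.  The clinical covariate table
    is available from :func:`cohort_covariates` with the same spec.
    """
    lat_rng, _, noise_ss = _cohort_streams(spec)
    latents = _subject_latents(spec, lat_rng)
    comps = _voxel_compartments(geometry)
    sigma = 1.0 / spec.snr_b0
    half = geometry.shape[0] // 2
    children = noise_ss.spawn(sum(n for _, _, n in _subject_table(spec)))
    child_iter = iter(children)

    # cache noise-free signals per (compartment set, aniso, diffu) signature
    signal_cache: dict[tuple, np.ndarray] = {}

    # left-hemisphere labels receiving the patient modulation: WM (bundle
    # corridors, CC) plus the designated GM regions
    affected_labels = {
        geometry.labels_for(name)[0]
        for name in spec.affected_rois
        if name in geometry.region_names
    }
    parc = geometry.parcellation

    def voxel_affected(vox) -> bool:
        if vox[0] >= half:
            return False
        label = int(parc[vox])
        if label == 0 or label == geometry.cc_label:
            return True  # WM corridor or corpus callosum
        return label in affected_labels

    for subject, group, n_sessions in _subject_table(spec):
        subj_diff = 1.0 + latents[(subject, "md")]
        subj_anis = 1.0 + 0.5 * latents[(subject, "fa")]
        for session in range(1, n_sessions + 1):
            child = next(child_iter)
            noise_rng = np.random.default_rng(child)
            vol = np.zeros(geometry.shape + (scheme.n_samples,), dtype=np.float32)
            aniso_eff = spec.effect(group, "fa", session)
            diffu_eff = spec.effect(group, "md", session)
            for vox, clist in comps.items():
                aniso = subj_anis
                diffu = subj_diff
                if group == "patient" and voxel_affected(vox):
                    aniso *= aniso_eff
                    diffu *= diffu_eff
                key = (
                    tuple((c.eigenvalues, c.orientation, c.volume_fraction) for c in clist),
                    round(aniso, 10),
                    round(diffu, 10),
                )
                sig = signal_cache.get(key)
                if sig is None:
                    mod = [_modulate(c, aniso, diffu) for c in clist]
                    sig = simulate_voxel_signal(mod, scheme)
                    signal_cache[key] = sig
                vol[vox] = sig
            flat = vol.reshape(-1, scheme.n_samples)
            noisy = add_rician_noise(flat.ravel(), sigma, noise_rng)
            vol = noisy.reshape(vol.shape).astype(np.float32)
            yield {"subject": subject, "group": group, "session": session}, vol


def cohort_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Clinical covariate table matching :func:`build_cohort` /
    :func:`simulate_measure_table` for the same spec (identical latent
    draws given the same seed)."""
    lat_rng, cov_rng, _ = _cohort_streams(spec)
    latents = _subject_latents(spec, lat_rng)
    return _covariates(spec, latents, cov_rng)
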