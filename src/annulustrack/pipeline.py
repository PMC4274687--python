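"""End-to-end segmentation pipeline and sensitivity protocols.

The method runs in two phases.  The *stiff* phase removes all deformation
states and tracks only the 7 global pose states, sweeping the filter twice
over the cycle (a warm-up sweep for rough convergence, then the recorded
sweep) with a constant rest state and process noise.  The *deformable*
phase reintroduces the 30 radial deformation states, uses the per-frame
stiff pose and covariance as the motion model's rest state and process
noise, tracks the cycle forward and backward, and fuses the passes by
precision weighting.  The annulus is measured on the assimilated surfaces
and mid-systole is the frame of maximum fitted annulus area.

Sensitivity protocols rerun the whole pipeline under randomized
perturbations of the initial pose (translation direction/magnitude,
rotation axis/angle) or a sweep of the assumed initial annulus diameter,
and summarize the spread of the resulting perimeter-derived diameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import annulus as ann
from . import edges as edgemod
from . import kalman, transform
from .io import VolumeSequence
from .mesh import SubdivisionSurface, limit_shrink_factor, make_default_mesh

__all__ = [
    "InitConfig",
    "PhaseConfig",
    "SegmentationResult",
    "SegmentationFailure",
    "default_stiff_config",
    "default_deform_config",
    "run_stiff",
    "run_deformable",
    "segment",
    "sensitivity_analysis",
]

N_GLOBAL = transform.N_GLOBAL


class SegmentationFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class InitConfig:
    """Initialization: estimated LVOT long axis (unit, image space), rough
    annulus center (mm) and the assumed annulus diameter / model length."""

    lvot_axis: np.ndarray
    annulus_center: np.ndarray
    init_diameter: float = 25.0
    init_length: float = 40.0

    def __post_init__(self):
        object.__setattr__(
            self, "lvot_axis", np.asarray(self.lvot_axis, dtype=float)
        )
        object.__setattr__(
            self, "annulus_center", np.asarray(self.annulus_center, dtype=float)
        )
        n = np.linalg.norm(self.lvot_axis)
        if n == 0:
            raise ValueError("lvot_axis must be nonzero")
        object.__setattr__(self, "lvot_axis", self.lvot_axis / n)
        if not (10.0 <= self.init_diameter <= 50.0):
            raise ValueError("init_diameter outside the plausible 10-50 mm range")


@dataclass(frozen=True)
class PhaseConfig:
    """Per-phase filter tuning: regularization gains per state class,
    process-noise standard deviations, and the edge-detection settings."""

    a_translation: float = 0.9
    a_scale: float = 0.95
    a_rotation: float = 0.9
    a_deform: float = 0.7
    q_translation: float = 2.0  # mm
    q_scale: float = 0.05
    q_rotation: float = np.deg2rad(3.0)  # rad
    q_deform: float = 1.0  # mm
    p0_translation: float = 10.0  # mm
    p0_scale: float = 0.2
    p0_rotation: float = 0.2  # rad
    p0_deform: float = 4.0  # mm
    n_warmup: int = 1
    n_tube: int = 300
    n_disc: int = 40
    edge: edgemod.EdgeConfig = field(default_factory=edgemod.EdgeConfig)


def default_stiff_config() -> PhaseConfig:
    return PhaseConfig()


def default_deform_config() -> PhaseConfig:
    """Deformable-phase defaults: stronger regularization on the global
    states (their confidence comes from the stiff pass) and a tighter edge
    search now that the model is roughly aligned."""
    return PhaseConfig(
        a_translation=0.98,
        a_scale=0.98,
        a_rotation=0.98,
        a_deform=0.7,
        n_warmup=2,
        edge=edgemod.EdgeConfig(
            search_length_mm=7.0, n_samples=21, peak_halfwidth=1
        ),
    )


@dataclass
class SegmentationResult:
    states: list  # per-frame assimilated FilterState
    meshes: list  # per-frame (verts, faces) in image space
    annulus: list  # per-frame AnnulusResult
    mid_systole: int | None
    diagnostics: dict
    status: str = "ok"


# ---------------------------------------------------------------------------
# Measurement assembly


def _neighbor_index_table(n_theta: int, n_axial: int, n_disc: int) -> np.ndarray:
    """(n, 4) array of neighbor sample indices (-1 padded): 4-neighborhood
    on the tube grid (angular wrap), ring neighbors on the disc."""
    n_tube = n_theta * n_axial
    nbr = np.full((n_tube + n_disc, 4), -1, dtype=np.int64)
    for i in range(n_theta):
        for j in range(n_axial):
            s = i * n_axial + j
            nbr[s, 0] = ((i - 1) % n_theta) * n_axial + j
            nbr[s, 1] = ((i + 1) % n_theta) * n_axial + j
            if j > 0:
                nbr[s, 2] = s - 1
            if j < n_axial - 1:
                nbr[s, 3] = s + 1
    for d in range(n_disc):
        s = n_tube + d
        nbr[s, 0] = n_tube + (d - 1) % n_disc
        nbr[s, 1] = n_tube + (d + 1) % n_disc
    return nbr


def _reject_outliers_mask(
    v: np.ndarray,
    height: np.ndarray,
    ok: np.ndarray,
    nbr: np.ndarray,
    min_step_height: float,
    max_delta: float,
) -> np.ndarray:
    """Vectorized one-sweep outlier rejection (pre-sweep neighbor stats)."""
    acc = ok & (height >= min_step_height)
    vn = np.where(acc, v, np.nan)
    padded = np.concatenate([vn, [np.nan]])
    neigh = padded[nbr]  # (n, 4); -1 picks the trailing NaN
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(neigh, axis=1)
    dev_ok = np.isnan(med) | (np.abs(v - med) <= max_delta)
    return acc & dev_ok


class _FrameMeasurer:
    """Caches sampling machinery for one phase and assembles per-frame
    measurement matrices (H, v, r)."""

    def __init__(
        self,
        seq: VolumeSequence,
        surf: SubdivisionSurface,
        cfg: PhaseConfig,
        deformable: bool,
    ):
        self.seq = seq
        self.surf = surf
        self.cfg = cfg
        self.deformable = deformable
        self.dirs = surf.mesh.deformation_dirs
        self.n_local = surf.mesh.n_points if deformable else 0
        self.nbr = _neighbor_index_table(
            surf.n_theta, surf.n_axial, len(surf.disc_points)
        )
        self.min_step_height = cfg.edge.min_step_frac * edgemod.robust_intensity_range(
            seq.frames[0]
        )
        self._static = None
        if not deformable:
            self._static = surf.sample_batch(np.zeros(surf.mesh.n_points))

    def measure(self, k: int, x: np.ndarray):
        """Returns (H, v, r, n_accepted) for frame k at predicted state x."""
        if self.deformable:
            x_l = x[N_GLOBAL:]
            P_t, N_t, Ws = self.surf.sample_batch(x_l)
            disc_normals = self.surf.disc_normals_radial
        else:
            P_t, N_t, Ws = self._static
            disc_normals = self.surf.disc_normals_axial
        P_l = np.concatenate([P_t, self.surf.disc_points])
        N_l = np.concatenate([N_t, disc_normals])
        if self.deformable:
            Ws_full = np.concatenate(
                [Ws, np.zeros((len(self.surf.disc_points), Ws.shape[1]))]
            )
            P_g, N_g, H = transform.measurement_vectors(
                x[: N_GLOBAL + self.n_local], P_l, N_l, Ws_full, self.dirs
            )
        else:
            P_g, N_g, H = transform.measurement_vectors(
                x[:N_GLOBAL], P_l, N_l, None, None
            )
        X, usable = edgemod.extract_profiles(
            self.seq.frames[k],
            self.seq.spacing,
            self.seq.origin,
            P_g,
            N_g,
            self.cfg.edge,
        )
        offs = self.cfg.edge.offsets()
        n_tube = len(P_l) - len(self.surf.disc_points)
        v_t, res_t, h_t, ok_t = edgemod.fit_edges(X[:n_tube], offs, self.cfg.edge)
        # disc probes look for the echogenic annulus band along the disc
        # normal: a peak, never a step (a step fit would latch onto broad
        # bright plateaus up or down the root)
        disc_cfg = replace(self.cfg.edge, fit_model="peak")
        v_d, res_d, h_d, ok_d = edgemod.fit_edges(X[n_tube:], offs, disc_cfg)
        v = np.concatenate([v_t, v_d])
        res = np.concatenate([res_t, res_d])
        h = np.concatenate([h_t, h_d])
        ok = np.concatenate([ok_t, ok_d]) & usable
        acc = _reject_outliers_mask(
            v,
            h,
            ok,
            self.nbr,
            self.min_step_height,
            self.cfg.edge.neighbor_max_delta_mm,
        )
        n_acc = int(acc.sum())
        if n_acc == 0:
            return None, None, None, 0
        r = edgemod.normalized_variances(res[acc], self.cfg.edge.r_edge)
        return H[acc], v[acc], r, n_acc


def _phase_vectors(cfg: PhaseConfig, n_local: int):
    a = np.concatenate(
        [
            np.full(3, cfg.a_translation),
            [cfg.a_scale],
            np.full(3, cfg.a_rotation),
            np.full(n_local, cfg.a_deform),
        ]
    )
    q = np.concatenate(
        [
            np.full(3, cfg.q_translation**2),
            [cfg.q_scale**2],
            np.full(3, cfg.q_rotation**2),
            np.full(n_local, cfg.q_deform**2),
        ]
    )
    p0 = np.concatenate(
        [
            np.full(3, cfg.p0_translation**2),
            [cfg.p0_scale**2],
            np.full(3, cfg.p0_rotation**2),
            np.full(n_local, cfg.p0_deform**2),
        ]
    )
    return a, q, p0


def _initial_pose(init: InitConfig) -> np.ndarray:
    x = np.zeros(N_GLOBAL)
    x[0:3] = init.annulus_center
    x[3] = 1.0
    x[4:7] = transform.axis_to_euler(init.lvot_axis)
    return x


def build_surface(init: InitConfig, cfg: PhaseConfig) -> SubdivisionSurface:
    """Control net posed so the rendered limit surface (not the control
    cage, which circumscribes it) has the requested annulus diameter."""
    shrink = limit_shrink_factor()
    mesh = make_default_mesh(init.init_diameter / shrink, init.init_length)
    return SubdivisionSurface(mesh, n_tube=cfg.n_tube, n_disc=cfg.n_disc)


# ---------------------------------------------------------------------------
# Phases


def run_stiff(
    seq: VolumeSequence,
    init: InitConfig,
    cfg: PhaseConfig | None = None,
    surf: SubdivisionSurface | None = None,
):
    """Stiff pass: global 7-state tracking, one warm-up sweep plus one
    recorded sweep with a constant motion model.

    Returns (states, surf, diagnostics): per-frame FilterState of the pose.
    """
    cfg = cfg or default_stiff_config()
    if seq.n_frames == 0:
        raise SegmentationFailure("empty sequence")
    if surf is None:
        surf = build_surface(init, cfg)
    meas = _FrameMeasurer(seq, surf, cfg, deformable=False)
    a, q, p0 = _phase_vectors(cfg, 0)
    x_init = _initial_pose(init)
    model = kalman.MotionModel(a=a, x0=x_init, Q0=q)
    state = kalman.FilterState(x=x_init.copy(), P=np.diag(p0), frame=0)
    edge_counts = []
    recorded = []
    for sweep in range(cfg.n_warmup + 1):
        record = sweep == cfg.n_warmup
        for k in range(seq.n_frames):
            state = kalman.predict(state, model, k)
            H, v, r, n_acc = meas.measure(k, state.x)
            if n_acc:
                state = kalman.update(state, H, v, r)
            if record:
                edge_counts.append(n_acc)
                recorded.append(
                    kalman.FilterState(x=state.x.copy(), P=state.P.copy(), frame=k)
                )
    n_probes = cfg.n_tube + cfg.n_disc
    n_empty = sum(1 for c in edge_counts if c < 0.1 * n_probes)
    diagnostics = {"stiff_edge_counts": edge_counts, "stiff_empty_frames": n_empty}
    if n_empty > seq.n_frames / 2:
        raise SegmentationFailure(
            f"stiff pass found almost no usable edges in {n_empty}/{seq.n_frames} frames"
        )
    return recorded, surf, diagnostics


def _track_pass(seq, meas, model, init_state, order, n_warmup: int = 0):
    states = []
    state = init_state
    counts = []
    # warm-start: iterate the pass's first frame so the recorded sweep does
    # not begin from the undeformed model (same role as the stiff phase's
    # warm-up sweep, confined to one frame)
    first = next(iter(order))
    for _ in range(n_warmup):
        st = kalman.predict(state, model, first)
        H, v, r, n_acc = meas.measure(first, st.x)
        state = kalman.update(st, H, v, r) if n_acc else st
    for k in order:
        state = kalman.predict(state, model, k)
        H, v, r, n_acc = meas.measure(k, state.x)
        if n_acc:
            state = kalman.update(state, H, v, r)
        counts.append(n_acc)
        states.append(kalman.FilterState(x=state.x.copy(), P=state.P.copy(), frame=k))
    return states, counts


def run_deformable(
    seq: VolumeSequence,
    stiff_states: list,
    surf: SubdivisionSurface,
    cfg: PhaseConfig | None = None,
    diagnostics: dict | None = None,
) -> SegmentationResult:
    """Deformable pass: full 37-state bidirectional tracking seeded by the
    stiff result, precision-weighted assimilation, and per-frame annulus
    measurement."""
    cfg = cfg or default_deform_config()
    n_local = surf.mesh.n_points
    dim = N_GLOBAL + n_local
    a, qvec, p0 = _phase_vectors(cfg, n_local)
    meas = _FrameMeasurer(seq, surf, cfg, deformable=True)
    diagnostics = dict(diagnostics or {})

    x0_list, Q0_list = [], []
    for st in stiff_states:
        x0 = np.zeros(dim)
        x0[:N_GLOBAL] = st.x
        x0_list.append(x0)
        Q0 = np.zeros((dim, dim))
        Q0[:N_GLOBAL, :N_GLOBAL] = st.P
        Q0[N_GLOBAL:, N_GLOBAL:] = np.eye(n_local) * cfg.q_deform**2
        Q0_list.append(Q0)
    model = kalman.MotionModel(a=a, x0=x0_list, Q0=Q0_list)

    def _init_from(pose, pose_P):
        x = np.zeros(dim)
        x[:N_GLOBAL] = pose
        P = np.zeros((dim, dim))
        P[:N_GLOBAL, :N_GLOBAL] = pose_P
        P[N_GLOBAL:, N_GLOBAL:] = np.eye(n_local) * cfg.p0_deform**2
        return kalman.FilterState(x=x, P=P, frame=0)

    # both passes start from the component-wise median stiff pose: a single
    # frame's pose can be caught on a secondary edge attractor, and the
    # pass-initial pose dominates the heavily regularized global states
    med_pose = np.median(np.stack([st.x for st in stiff_states]), axis=0)
    med_P = np.median(np.stack([st.P for st in stiff_states]), axis=0)

    N = seq.n_frames
    fwd, cf = _track_pass(
        seq, meas, model, _init_from(med_pose, med_P), range(N), cfg.n_warmup
    )
    bwd, cb = _track_pass(
        seq,
        meas,
        model,
        _init_from(med_pose, med_P),
        range(N - 1, -1, -1),
        cfg.n_warmup,
    )
    bwd = list(reversed(bwd))
    fused = kalman.assimilate(fwd, bwd)
    diagnostics["deform_edge_counts_fwd"] = cf
    diagnostics["deform_edge_counts_bwd"] = list(reversed(cb))

    meshes, results = [], []
    for st in fused:
        x_g, x_l = st.x[:N_GLOBAL], st.x[N_GLOBAL:]
        verts_l = surf.refined_verts(x_l)
        verts_g = transform.transform_point(x_g, verts_l)
        meshes.append((verts_g, surf.faces))
        results.append(_measure_annulus(st.frame, x_g, x_l, surf))
    try:
        mid = ann.select_mid_systole(results)
    except ann.AnnulusFailure as exc:
        raise SegmentationFailure(str(exc)) from exc
    return SegmentationResult(
        states=fused,
        meshes=meshes,
        annulus=results,
        mid_systole=mid,
        diagnostics=diagnostics,
        status="ok",
    )


def _measure_annulus(k: int, x_g, x_l, surf) -> ann.AnnulusResult:
    """Intersect the deformed surface with the disc plane in the model frame
    and map the fitted ellipse through the similarity transform (a uniform
    scale s multiplies both semi-axes; rotation and translation move the
    center and plane normal)."""
    ring = surf.annulus_ring(x_l)
    s = float(x_g[3])
    R = transform.rotation_matrix(x_g[4:7])
    normal = R @ np.array([0.0, 0.0, 1.0])
    try:
        if len(ring) < 5:
            raise ann.AnnulusFailure("too few intersection points")
        par = ann.fit_ellipse_2d(ring[:, :2])
        m = ann.ellipse_measures(
            ann.EllipseParams(center=par.center, a=s * par.a, b=s * par.b, phi=par.phi)
        )
    except (ann.AnnulusFailure, ValueError):
        return ann.AnnulusResult(
            frame_index=k,
            center=np.full(3, np.nan),
            normal=normal,
            major_d=np.nan,
            minor_d=np.nan,
            area=np.nan,
            perimeter=np.nan,
            area_derived_d=np.nan,
            perimeter_derived_d=np.nan,
            valid=False,
        )
    center_l = np.array([par.center[0], par.center[1], 0.0])
    center_g = transform.transform_point(x_g, center_l)
    return ann.AnnulusResult(
        frame_index=k,
        center=center_g,
        normal=normal,
        major_d=m["major_d"],
        minor_d=m["minor_d"],
        area=m["area"],
        perimeter=m["perimeter"],
        area_derived_d=m["area_derived_d"],
        perimeter_derived_d=m["perimeter_derived_d"],
        valid=True,
    )


def renormalize_stiff_scale(
    stiff_states: list, init: InitConfig, cfg: PhaseConfig
):
    """Absorb the converged stiff scale into the control-net geometry.

    The scale state multiplies the whole model, radius and length alike, so
    a poor initial diameter guess leaves the converged model with a
    stretched or compressed ring spacing and hence a different axial
    smoothing of the radius profile.  Rebuilding the net at the fitted size
    (median scale over frames) and dividing the per-frame scales out makes
    the deformable phase geometry independent of the initial guess.
    """
    s_bar = float(np.median([st.x[3] for st in stiff_states]))
    fitted = float(np.clip(init.init_diameter * s_bar, 10.0, 50.0))
    new_init = replace(init, init_diameter=fitted)
    surf = build_surface(new_init, cfg)
    D = np.ones(N_GLOBAL)
    D[3] = 1.0 / s_bar
    out = []
    for st in stiff_states:
        x = st.x.copy()
        x[3] /= s_bar
        P = (D[:, None] * st.P) * D[None, :]
        out.append(kalman.FilterState(x=x, P=P, frame=st.frame))
    return out, surf


def segment(
    seq: VolumeSequence,
    init: InitConfig,
    cfg_stiff: PhaseConfig | None = None,
    cfg_deform: PhaseConfig | None = None,
    strict: bool = False,
) -> SegmentationResult:
    """Full two-phase segmentation.  On failure returns a result object with
    ``status='failed'`` and diagnostics (or raises when ``strict``)."""
    try:
        stiff_states, surf, diag = run_stiff(seq, init, cfg_stiff)
        stiff_states, surf = renormalize_stiff_scale(
            stiff_states, init, cfg_deform or default_deform_config()
        )
        return run_deformable(seq, stiff_states, surf, cfg_deform, diag)
    except SegmentationFailure as exc:
        if strict:
            raise
        return SegmentationResult(
            states=[],
            meshes=[],
            annulus=[],
            mid_systole=None,
            diagnostics={"error": str(exc)},
            status="failed",
        )


# ---------------------------------------------------------------------------
# Sensitivity protocols


def _random_unit(rng) -> np.ndarray:
    """Unit vector with components drawn uniformly on [-1, 1]."""
    while True:
        n = rng.uniform(-1.0, 1.0, size=3)
        nn = np.linalg.norm(n)
        if nn > 1e-9:
            return n / nn


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def perturb_translation(init: InitConfig, d: float, rng) -> InitConfig:
    n = _random_unit(rng)
    return replace(init, annulus_center=init.annulus_center + d * n)


def perturb_rotation(init: InitConfig, phi_deg: float, rng) -> InitConfig:
    """Rotate the initial model by phi about a random line through the
    initial annulus center (the center itself is invariant)."""
    axis = _random_unit(rng)
    Rp = _axis_angle_matrix(axis, np.deg2rad(phi_deg))
    return replace(init, lvot_axis=Rp @ init.lvot_axis)


def sensitivity_analysis(
    seq: VolumeSequence,
    init: InitConfig,
    protocol: str,
    magnitudes=None,
    n_reps: int = 50,
    seed: int = 0,
    cfg_stiff: PhaseConfig | None = None,
    cfg_deform: PhaseConfig | None = None,
) -> dict:
    """Rerun the full segmentation under perturbed initializations.

    protocol "translation": magnitudes are offsets d (mm), default
    2,4,...,12; "rotation": angles phi (deg), default 1..15; "scaling":
    initial diameters D0 (mm), default 100 values in [15, 35] (deterministic,
    one run each).  Returns per-magnitude mean/SD of the mid-systole
    perimeter-derived diameter; failed runs are recorded as missing.
    """
    if protocol not in ("translation", "rotation", "scaling"):
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = np.random.default_rng(seed)
    if magnitudes is None:
        magnitudes = {
            "translation": np.arange(2.0, 13.0, 2.0),
            "rotation": np.arange(1.0, 16.0),
            "scaling": np.linspace(15.0, 35.0, 100),
        }[protocol]
    magnitudes = np.asarray(magnitudes, dtype=float)

    out = {"protocol": protocol, "magnitudes": magnitudes, "per_magnitude": []}
    for mag in magnitudes:
        diams = []
        n_runs = 1 if protocol == "scaling" else n_reps
        for _ in range(n_runs):
            if protocol == "translation":
                pinit = perturb_translation(init, mag, rng)
            elif protocol == "rotation":
                pinit = perturb_rotation(init, mag, rng)
            else:
                pinit = replace(init, init_diameter=float(mag))
            res = segment(seq, pinit, cfg_stiff, cfg_deform)
            if res.status == "ok" and res.mid_systole is not None:
                diams.append(res.annulus[res.mid_systole].perimeter_derived_d)
            else:
                diams.append(np.nan)
        diams = np.asarray(diams)
        good = diams[np.isfinite(diams)]
        out["per_magnitude"].append(
            {
                "magnitude": float(mag),
                "n": int(good.size),
                "n_failed": int(diams.size - good.size),
                "mean": float(good.mean()) if good.size else np.nan,
                "sd": float(good.std(ddof=1)) if good.size > 1 else 0.0,
                "diameters": diams,
            }
        )
    if protocol == "scaling":
        all_d = np.concatenate([m["diameters"] for m in out["per_magnitude"]])
        good = all_d[np.isfinite(all_d)]
        out["overall_sd"] = float(good.std(ddof=1)) if good.size > 1 else 0.0
        out["overall_mean"] = float(good.mean()) if good.size else np.nan
    return out
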