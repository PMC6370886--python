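"""Rendering of ground truth into two-channel fluorescence volumes.

Chromatin channel: each nucleus is a soft-edged ellipsoid whose radius,
brightness and internal texture follow the cell-cycle phase —

* S: large, dim, smooth (decondensed chromatin)
* prophase: shrinking, brightening, coarsening texture
* prometaphase/metaphase: compact, bright, strongly textured plate
* anaphase: two compact masses separating toward the daughter positions
* telophase: re-expanding daughter

Active transcription sites punch a multiplicative "hole" (chromatin
depletion) of configurable radius into the chromatin signal, with depth
following the focus volume profile.

Transcript channel: each focus is a near-uniform sphere whose volume follows
the rise/plateau/residual/decay profile, with a Gaussian-smoothed boundary
standing in for the optics.  Poisson (shot) plus Gaussian (read) noise and a
constant background complete the camera model.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .movie import Movie
from .simconfig import SimConfig
from .truth import GroundTruth
from .lineage import focus_volume

CHANNELS = ("h2b", "mo")    # chromatin marker, transcript label

#: (radius factor, amplitude, texture sd) anchors per phase
_PHASE_STYLE = {
    "telophase": (0.72, 160.0, 9.0),
    "S": (1.0, 200.0, 7.0),
    "prophase": (0.78, 250.0, 32.0),
    "prometaphase": (0.62, 340.0, 55.0),
    "metaphase": (0.52, 400.0, 70.0),
    "anaphase": (0.45, 380.0, 60.0),
}
_FOCUS_AMP = 300.0
_HOLE_MAX_DEPTH = 0.9      # fraction of chromatin removed at full plateau
_PSF_SIGMA_UM = (0.4, 0.4, 0.5)   # (x, y, z)


def _draw_blob(vol: np.ndarray, centre_um, semi_um, amp: float,
               voxel, tex_sd: float = 0.0, rng=None) -> None:
    """Add a uniform (optionally textured) ellipsoid into ``vol`` in place."""
    vx, vy, vz = voxel
    cx, cy, cz = centre_um
    ax, ay, az = semi_um
    nz, ny, nx = vol.shape
    x0 = max(int((cx - ax) / vx) - 1, 0)
    x1 = min(int((cx + ax) / vx) + 2, nx)
    y0 = max(int((cy - ay) / vy) - 1, 0)
    y1 = min(int((cy + ay) / vy) + 2, ny)
    z0 = max(int((cz - az) / vz) - 1, 0)
    z1 = min(int((cz + az) / vz) + 2, nz)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz = (np.arange(z0, z1) * vz - cz) / az
    yy = (np.arange(y0, y1) * vy - cy) / ay
    xx = (np.arange(x0, x1) * vx - cx) / ax
    rho2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2)
    mask = rho2 <= 1.0
    sub = vol[z0:z1, y0:y1, x0:x1]
    add = np.zeros_like(sub)
    add[mask] = amp
    if tex_sd > 0 and rng is not None:
        add[mask] += rng.normal(0.0, tex_sd, int(mask.sum()))
    sub += add


def _apply_hole(vol: np.ndarray, centre_um, radius_um: float,
                depth: float, voxel) -> None:
    """Multiply a spherical region by ``1 - depth`` (chromatin depletion)."""
    vx, vy, vz = voxel
    cx, cy, cz = centre_um
    nz, ny, nx = vol.shape
    x0 = max(int((cx - radius_um) / vx) - 1, 0)
    x1 = min(int((cx + radius_um) / vx) + 2, nx)
    y0 = max(int((cy - radius_um) / vy) - 1, 0)
    y1 = min(int((cy + radius_um) / vy) + 2, ny)
    z0 = max(int((cz - radius_um) / vz) - 1, 0)
    z1 = min(int((cz + radius_um) / vz) + 2, nz)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz = np.arange(z0, z1) * vz - cz
    yy = np.arange(y0, y1) * vy - cy
    xx = np.arange(x0, x1) * vx - cx
    rho2 = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2
            + xx[None, None, :] ** 2)
    mask = rho2 <= radius_um ** 2
    sub = vol[z0:z1, y0:y1, x0:x1]
    sub[mask] *= (1.0 - depth)


def _phase_and_progress(n, t: float, config: SimConfig):
    """Phase label and within-phase progress in [0, 1] for nucleus row ``n``."""
    fr_p, fr_pm, fr_m, fr_a, fr_t = config.m_subphase_fracs
    m_s = config.m_phase_s
    telo_end = n.birth_s + fr_t * m_s
    s_end = telo_end + n.s_len_s
    pro_end = s_end + fr_p * m_s
    pm_end = pro_end + fr_pm * m_s
    meta_end = pm_end + fr_m * m_s
    for phase, a, b in (("telophase", n.birth_s, telo_end), ("S", telo_end, s_end),
                        ("prophase", s_end, pro_end), ("prometaphase", pro_end, pm_end),
                        ("metaphase", pm_end, meta_end),
                        ("anaphase", n.division_s, n.ana_end_s)):
        if a <= t < b:
            return phase, (t - a) / max(b - a, 1e-9)
    return None, 0.0


def render_movie(truth: GroundTruth, config: SimConfig) -> Movie:
    """Render a complete two-channel movie from assigned ground truth.

    Deterministic given ``config`` (noise streams are keyed on
    ``(seed, frame)``).  Raises if expression has not been assigned.
    """
    config.validate()
    if truth.expression is None:
        raise ValueError("assign_expression must run before rendering")
    nz, ny, nx = config.field_shape
    vx, vy, vz = config.voxel_size_um
    voxel = (vx, vy, vz)
    n_frames = truth.n_frames
    data = np.zeros((n_frames, 2, nz, ny, nx), dtype=np.uint16)

    nuclei = truth.nuclei
    expr_by_id = {int(r.nucleus_id): r for _, r in truth.expression.iterrows()}
    sites_by_id: dict[int, np.ndarray] = {}
    if truth.sites is not None and len(truth.sites):
        for nid, grp in truth.sites.groupby("nucleus_id"):
            g = grp.sort_values("allele")
            sites_by_id[int(nid)] = g[["x_um", "y_um", "z_um"]].to_numpy()
    daughters_of: dict[int, list[np.ndarray]] = {}
    for _, d in nuclei[nuclei.mother_id >= 0].iterrows():
        daughters_of.setdefault(int(d.mother_id), []).append(
            np.array([d.x_um, d.y_um, d.z_um]))

    sigma_vox = (_PSF_SIGMA_UM[2] / vz, _PSF_SIGMA_UM[1] / vy,
                 _PSF_SIGMA_UM[0] / vx)
    noise = config.noise

    for k in range(n_frames):
        t = k * config.frame_interval_s
        rng = np.random.default_rng([config.seed % (2 ** 31), 7, k])
        chrom = np.zeros((nz, ny, nx), dtype=np.float32)
        mo = np.zeros((nz, ny, nx), dtype=np.float32)
        alive = nuclei[(nuclei.birth_s <= t) & (t < nuclei.ana_end_s)]
        holes: list[tuple[np.ndarray, float]] = []
        for _, n in alive.sort_values("nucleus_id").iterrows():
            phase, prog = _phase_and_progress(n, t, config)
            if phase is None:
                continue
            r = n.radius_um
            centre = np.array([n.x_um, n.y_um, n.z_um])
            if phase == "anaphase":
                factor, amp, tex = _PHASE_STYLE["anaphase"]
                kids = daughters_of.get(int(n.nucleus_id))
                if kids is None:    # leaf: separate along a per-nucleus axis
                    theta = np.random.default_rng(
                        [config.seed % (2 ** 31), 3, int(n.nucleus_id)]
                    ).uniform(0, 2 * np.pi)
                    u = np.array([np.cos(theta), np.sin(theta), 0.0])
                    kids = [centre + 1.15 * r * u, centre - 1.15 * r * u]
                for kid in kids:
                    c = centre + prog * (np.asarray(kid) - centre)
                    semi = (factor * r, factor * r, 0.8 * factor * r)
                    _draw_blob(chrom, c, semi, amp, voxel, tex, rng)
            else:
                f0, amp0, tex0 = _PHASE_STYLE[phase]
                if phase == "telophase":
                    # decompaction accelerates: most of the re-expansion
                    # happens in the second half of telophase
                    p = prog ** 1.6
                    f1, amp1, tex1 = _PHASE_STYLE["S"]
                    f = f0 + (f1 - f0) * p
                    amp = amp0 + (amp1 - amp0) * p
                    tex = tex0 + (tex1 - tex0) * p
                elif phase == "prophase":
                    # condensation sets in quickly at prophase entry
                    p = np.sqrt(prog)
                    fs, amps, texs = _PHASE_STYLE["S"]
                    f = fs + (f0 - fs) * p
                    amp = amps + (amp0 - amps) * p
                    tex = texs + (tex0 - texs) * p
                else:
                    f, amp, tex = f0, amp0, tex0
                semi = (f * r, f * r, 0.8 * f * r)
                _draw_blob(chrom, centre, semi, amp, voxel, tex, rng)
            # transcription foci + chromatin holes
            e = expr_by_id.get(int(n.nucleus_id))
            if e is not None:
                v = focus_volume(e, t, config)
                if v > 0:
                    rf = (3 * v / (4 * np.pi)) ** (1 / 3)
                    for site in sites_by_id[int(n.nucleus_id)]:
                        _draw_blob(mo, site, (rf, rf, rf), _FOCUS_AMP, voxel)
                        holes.append(
                            (site,
                             _HOLE_MAX_DEPTH * min(v / config.peak_volume_um3, 1.0)))
        for site, depth in holes:
            _apply_hole(chrom, site, config.hole_radius_um, depth, voxel)

        for ci, img in enumerate((chrom, mo)):
            img = ndi.gaussian_filter(img, sigma_vox)
            img += noise.background
            if noise.photon_scale > 0:
                img = rng.poisson(
                    np.maximum(img, 0.0) / noise.photon_scale
                ).astype(np.float32) * noise.photon_scale
            if noise.gaussian_sd > 0:
                img = img + rng.normal(0.0, noise.gaussian_sd, img.shape)
            data[k, ci] = np.clip(img, 0, 65535).astype(np.uint16)

    return Movie(data=data, channel_names=CHANNELS,
                 voxel_size_um=config.voxel_size_um,
                 frame_interval_s=config.frame_interval_s)
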