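"""Lineage, cell-cycle timing and expression assignment for the synthetic
embryo.

The model: founder nuclei sit on a patch of the animal pole (rendered as a
flat field; blastomere nuclei at these stages form a near-monolayer cap).
Divisions are metasynchronous — each founder's clock is offset by a wave
delay proportional to its position along the x axis — and cycle lengths are
drawn per generation from a normal distribution whose mean increases
generation by generation while M-phase stays constant, so all cycle
elongation is S-phase elongation.  A chk1-like perturbation multiplies
S-phase length by a constant factor and leaves M untouched; a
triptolide-like perturbation switches transcription off without touching
the cell cycle.

From the onset generation on, each nucleus expresses with a baseline
probability, plus an additive boost when its mother expressed (lineage
memory).  Expression starts with a random fractional delay into S-phase and
its detectable span scales with S-phase length, with a residual
(lower-volume) tail into prophase-metaphase.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simconfig import SimConfig, ConfigError
from .truth import GroundTruth, PHASE_ORDER

_T0_S = 60.0          # time of the first founder's birth (telophase start)
_RAMP_DOWN_S = 60.0   # peak -> residual volume ramp at prophase entry


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _field_extent_um(config: SimConfig) -> tuple[float, float, float]:
    nz, ny, nx = config.field_shape
    vx, vy, vz = config.voxel_size_um
    return nx * vx, ny * vy, nz * vz


def _place_founders(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Founder centres (n, 3) in µm (x, y, z), on a jittered grid."""
    w, h, depth = _field_extent_um(config)
    r = config.radius_um(0)
    margin = r + 2.0
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ConfigError("field too small to place founder nuclei without overlap")
    n = config.n_founders
    ncol = int(math.ceil(math.sqrt(n)))
    nrow = int(math.ceil(n / ncol))
    xs = np.linspace(margin, w - margin, ncol)
    ys = np.linspace(margin, h - margin, nrow)
    cells = [(x, y) for y in ys for x in xs]
    order = rng.permutation(len(cells))[:n]
    jitter_x = (xs[1] - xs[0]) * 0.2 if ncol > 1 else 1.0
    jitter_y = (ys[1] - ys[0]) * 0.2 if nrow > 1 else 1.0
    pos = np.empty((n, 3))
    for i, ci in enumerate(order):
        cx, cy = cells[ci]
        pos[i, 0] = np.clip(cx + rng.uniform(-jitter_x, jitter_x), margin, w - margin)
        pos[i, 1] = np.clip(cy + rng.uniform(-jitter_y, jitter_y), margin, h - margin)
        pos[i, 2] = depth / 2 + rng.uniform(-1.0, 1.0)
    return pos


def _relax(positions: np.ndarray, min_dist: float, bounds: tuple[float, float],
           margin: float, n_iter: int = 80) -> np.ndarray:
    """Push overlapping centres apart in the xy plane (z untouched)."""
    pos = positions.copy()
    w, h = bounds
    n = len(pos)
    if n < 2:
        pos[:, 0] = np.clip(pos[:, 0], margin, w - margin)
        pos[:, 1] = np.clip(pos[:, 1], margin, h - margin)
        return pos
    # exactly coincident centres (e.g. both clamped into a corner) would
    # receive no net push; a deterministic sub-nm stagger breaks the tie
    pos[:, 0] += 1e-3 * np.arange(n)
    pos[:, 1] -= 1e-3 * np.arange(n)
    for _ in range(n_iter):
        diff = pos[None, :, :2] - pos[:, None, :2]      # i -> j displacement
        dist = np.sqrt((diff ** 2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        close = dist < min_dist
        if not close.any():
            break
        safe = np.where(dist < 1e-9, 1.0, dist)
        unit = diff / safe[:, :, None]
        overlap = np.where(close, (min_dist - dist) / 2, 0.0)
        push = (unit * overlap[:, :, None]).sum(axis=1)
        pos[:, :2] -= push
        # reflect at the borders (clipping would re-collapse nuclei that
        # were both pushed into the same corner)
        for ax, hi in ((0, w), (1, h)):
            v = pos[:, ax]
            v[:] = np.where(v < margin, 2 * margin - v, v)
            v[:] = np.where(v > hi - margin, 2 * (hi - margin) - v, v)
            v[:] = np.clip(v, margin, hi - margin)
    return pos


# ---------------------------------------------------------------------------
# lineage
# ---------------------------------------------------------------------------

def build_lineage(config: SimConfig) -> GroundTruth:
    """Build the division tree with per-nucleus phase timelines and positions.

    Deterministic given ``config`` (including its seed).  Returns a
    :class:`GroundTruth` whose ``nuclei`` and ``phases`` tables are filled;
    expression is added by :func:`assign_expression`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    w, h, _depth = _field_extent_um(config)
    fr_p, fr_pm, fr_m, fr_a, fr_t = config.m_subphase_fracs
    m_s = config.m_phase_s
    ana_dur = fr_a * m_s
    telo_dur = fr_t * m_s

    founders = _place_founders(config, rng)
    rows: list[dict] = []
    next_id = 0
    cohort: list[dict] = []
    for i in range(config.n_founders):
        delay = founders[i, 0] / config.wave_speed_um_per_s
        cohort.append({
            "nucleus_id": next_id, "mother_id": -1, "generation": 0,
            "birth_s": _T0_S + delay, "pos": founders[i],
        })
        next_id += 1

    for gen in range(config.n_levels):
        r_g = config.radius_um(gen)
        mean_s = config.cycle_mean_min[gen] * 60.0
        sd_s = config.cycle_sd_min[gen] * 60.0
        for nuc in cohort:
            cycle = rng.normal(mean_s, sd_s)
            cycle = max(cycle, m_s + 30.0)   # keep S-phase physical
            s_len = cycle - m_s
            if config.perturbation == "chk1":
                s_len = s_len * config.chk1_s_scale
                cycle = s_len + m_s
            if s_len <= 0:
                raise ConfigError("non-positive S-phase length after perturbation")
            birth = nuc["birth_s"]
            division = birth - ana_dur + cycle       # anaphase start
            nuc.update({
                "division_s": division, "ana_end_s": division + ana_dur,
                "cycle_s": cycle, "s_len_s": s_len, "m_len_s": m_s,
                "radius_um": r_g,
            })
        # spawn and place daughters before committing this cohort
        daughters: list[dict] = []
        if gen < config.n_generations:
            r_child = config.radius_um(gen + 1)
            sep = 2.4 * r_child
            margin = r_child + 1.0
            raw = []
            for nuc in cohort:
                theta = rng.uniform(0, 2 * np.pi)
                u = np.array([np.cos(theta), np.sin(theta), 0.0])
                # near a border, damp the outward component of the division
                # axis so both daughters stay inside the field
                need = sep / 2 + margin
                if nuc["pos"][0] < need or nuc["pos"][0] > w - need:
                    u[0] *= 0.15
                if nuc["pos"][1] < need or nuc["pos"][1] > h - need:
                    u[1] *= 0.15
                norm = np.hypot(u[0], u[1])
                u[:2] /= norm if norm > 1e-9 else 1.0
                dz = rng.uniform(-0.5, 0.5)
                for sgn in (+1.0, -1.0):
                    p = nuc["pos"] + sgn * u * sep / 2
                    p[2] = nuc["pos"][2] + sgn * dz
                    raw.append(p)
            raw = np.array(raw)
            raw[:, 2] = np.clip(raw[:, 2], 2.0, _field_extent_um(config)[2] - 2.0)
            relaxed = _relax(raw, min_dist=2.25 * r_child, bounds=(w, h),
                             margin=margin)
            if len(relaxed) > 1:
                from scipy.spatial.distance import pdist
                if pdist(relaxed[:, :2]).min() < 1.6 * r_child:
                    raise ConfigError(
                        "field too small to place nuclei without overlap; "
                        "enlarge field_shape or reduce n_founders/n_generations")
            k = 0
            for nuc in cohort:
                for _ in range(2):
                    daughters.append({
                        "nucleus_id": next_id, "mother_id": nuc["nucleus_id"],
                        "generation": gen + 1, "birth_s": nuc["ana_end_s"],
                        "pos": relaxed[k],
                    })
                    next_id += 1
                    k += 1
        rows.extend(cohort)
        cohort = daughters

    nuclei = pd.DataFrame([{
        "nucleus_id": r["nucleus_id"], "mother_id": r["mother_id"],
        "generation": r["generation"], "birth_s": r["birth_s"],
        "division_s": r["division_s"], "ana_end_s": r["ana_end_s"],
        "cycle_s": r["cycle_s"], "s_len_s": r["s_len_s"], "m_len_s": r["m_len_s"],
        "x_um": r["pos"][0], "y_um": r["pos"][1], "z_um": r["pos"][2],
        "radius_um": r["radius_um"],
        "expressing": False, "onset_s": np.nan, "end_s": np.nan,
    } for r in rows])

    phases = _phase_table(nuclei, config)
    duration = float(nuclei.ana_end_s.max()) + 2 * config.frame_interval_s
    meta = {
        "seed": config.seed, "ploidy": config.ploidy,
        "perturbation": config.perturbation,
        "frame_interval_s": config.frame_interval_s,
        "n_frames": int(math.ceil(duration / config.frame_interval_s)),
        "field_shape": list(config.field_shape),
        "voxel_size_um": list(config.voxel_size_um),
        "config": config.to_dict(),
    }
    return GroundTruth(nuclei=nuclei, phases=phases, meta=meta)


def _phase_table(nuclei: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    fr_p, fr_pm, fr_m, fr_a, fr_t = config.m_subphase_fracs
    m_s = config.m_phase_s
    recs = []
    for _, n in nuclei.iterrows():
        t = n.birth_s
        telo_end = t + fr_t * m_s
        s_end = telo_end + n.s_len_s
        pro_end = s_end + fr_p * m_s
        pm_end = pro_end + fr_pm * m_s
        meta_end = pm_end + fr_m * m_s          # == division_s
        bounds = [
            ("telophase", t, telo_end),
            ("S", telo_end, s_end),
            ("prophase", s_end, pro_end),
            ("prometaphase", pro_end, pm_end),
            ("metaphase", pm_end, meta_end),
            ("anaphase", n.division_s, n.ana_end_s),
        ]
        for phase, a, b in bounds:
            recs.append({"nucleus_id": n.nucleus_id, "phase": phase,
                         "start_s": a, "end_s": b})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# expression + focus sites
# ---------------------------------------------------------------------------

def _site_offsets(ploidy: int, radius_um: float, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Focus-site offsets (ploidy, 3) from the nucleus centre, µm.

    One site per homologous chromosome territory; sites sit in the nuclear
    mid-plane at a minimum mutual separation of 2x the chromatin-hole radius
    (pairs opposite each other; tetraploid sets on a square).
    """
    r_focus = (3 * config.peak_volume_um3 / (4 * np.pi)) ** (1 / 3)
    reach = 0.8 * radius_um - r_focus
    if reach <= 0:
        raise ConfigError("nucleus too small to host transcription foci")
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    if ploidy == 2:
        d = min(4.0, 2 * reach)
        base = np.array([[d / 2, 0.0], [-d / 2, 0.0]])
    else:
        d = min(4.0, math.sqrt(2) * reach)
        base = np.array([[d / 2, d / 2], [d / 2, -d / 2],
                         [-d / 2, d / 2], [-d / 2, -d / 2]])
    if d < 1.9 * config.hole_radius_um:
        raise ConfigError("hole_radius_um too large for the nucleus geometry")
    rot = base @ np.array([[c, s], [-s, c]])
    zj = rng.uniform(-0.5, 0.5, size=len(base))
    return np.column_stack([rot, zj])


def assign_expression(truth: GroundTruth, config: SimConfig) -> GroundTruth:
    """Add expression on/off states, intervals, focus sites and the per-frame
    truth focus table to a built lineage.  Deterministic given config."""
    config.validate()
    if config.onset_generation > config.n_generations:
        raise ConfigError("onset_generation beyond the simulated range")
    rng = np.random.default_rng([config.seed, 1])
    fr_p, fr_pm, fr_m, fr_a, fr_t = config.m_subphase_fracs
    m_s = config.m_phase_s

    nuclei = truth.nuclei.copy()
    nuclei["expressing"] = False
    nuclei["onset_s"] = np.nan
    nuclei["end_s"] = np.nan
    expr_rows, site_rows = [], []
    expressed: dict[int, bool] = {}

    for _, n in nuclei.sort_values(["generation", "nucleus_id"]).iterrows():
        nid = int(n.nucleus_id)
        p = config.p_express
        if int(n.mother_id) >= 0 and expressed.get(int(n.mother_id), False):
            p = p + config.memory_boost
        if p > 1.0 + 1e-9:
            raise ConfigError("p_express + memory_boost exceeds 1")
        # draw consumed regardless of gating, keeps lineage-conditional
        # randomness aligned between perturbed and control runs
        u = rng.uniform()
        on = (n.generation >= config.onset_generation) and (u < p)
        if config.perturbation == "triptolide":
            on = False
        expressed[nid] = bool(on)
        if not on:
            continue

        telo_end = n.birth_s + fr_t * m_s       # S start
        s_end = telo_end + n.s_len_s            # prophase start
        meta_start = s_end + (fr_p + fr_pm) * m_s
        delay = rng.uniform(*config.onset_delay_frac) * n.s_len_s
        onset = telo_end + delay
        core_end = onset + config.span_coupling * (s_end - onset)
        if core_end >= s_end - 1e-9 and config.residual_m_frac > 0:
            mode = "residual"
            end = n.division_s                  # fades out at anaphase start
        else:
            mode = "decay"
            end = core_end + config.decay_min * 60.0
        end = min(end, n.division_s)
        nuclei.loc[nuclei.nucleus_id == nid, ["expressing", "onset_s", "end_s"]] = \
            [True, onset, end]
        expr_rows.append({
            "nucleus_id": nid, "onset_s": onset, "end_s": end,
            "span_s": end - onset, "onset_delay_s": delay,
            "s_start_s": telo_end, "s_end_s": s_end,
            "meta_start_s": meta_start, "division_s": n.division_s,
            "core_end_s": core_end, "mode": mode,
            "peak_um3": config.peak_volume_um3,
        })
        offsets = _site_offsets(config.ploidy, n.radius_um, config, rng)
        for allele in range(config.ploidy):
            site_rows.append({
                "nucleus_id": nid, "allele": allele,
                "x_um": n.x_um + offsets[allele, 0],
                "y_um": n.y_um + offsets[allele, 1],
                "z_um": n.z_um + offsets[allele, 2],
            })

    expression = pd.DataFrame(expr_rows)
    sites = pd.DataFrame(site_rows)
    out = GroundTruth(nuclei=nuclei, phases=truth.phases, meta=dict(truth.meta),
                      expression=expression, sites=sites)
    out.foci = _foci_table(out, config)
    return out


def focus_volume(expr_row, t_s: float, config: SimConfig) -> float:
    """Truth focus volume (µm³ per focus) of one expressing nucleus at ``t_s``.

    Piecewise profile: linear rise over ``rise_min`` to the plateau, plateau
    through S-phase, then either a residual shoulder (``residual_m_frac`` x
    peak) through prophase-metaphase fading to zero at anaphase, or a linear
    decay over ``decay_min`` when the detectable span ends within S.
    """
    onset = expr_row["onset_s"]
    end = expr_row["end_s"]
    peak = expr_row["peak_um3"]
    if t_s < onset or t_s >= end:
        return 0.0
    rise_s = config.rise_min * 60.0
    core_end = min(expr_row["core_end_s"], expr_row["s_end_s"])
    rise_end = min(onset + rise_s, core_end)
    if t_s < rise_end:
        return peak * (t_s - onset) / (rise_end - onset)
    if expr_row["mode"] == "residual":
        s_end = expr_row["s_end_s"]
        if t_s < s_end:
            return peak
        resid = config.residual_m_frac * peak
        ramp_end = min(s_end + _RAMP_DOWN_S, expr_row["meta_start_s"])
        if t_s < ramp_end:
            f = (t_s - s_end) / (ramp_end - s_end)
            return peak + f * (resid - peak)
        meta_start = expr_row["meta_start_s"]
        if t_s < meta_start:
            return resid
        return resid * max(0.0, (end - t_s) / (end - meta_start))
    # decay mode
    if t_s < core_end:
        return peak
    return peak * max(0.0, (end - t_s) / (end - core_end))


def _foci_table(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    rows = []
    if truth.expression is None or len(truth.expression) == 0:
        return pd.DataFrame(
            columns=["frame", "t_s", "nucleus_id", "allele",
                     "x_um", "y_um", "z_um", "volume_um3"])
    sites = truth.sites.set_index(["nucleus_id", "allele"])
    times = truth.frame_times()
    for _, e in truth.expression.iterrows():
        nid = int(e.nucleus_id)
        for k, t in enumerate(times):
            v = focus_volume(e, float(t), config)
            if v <= 0:
                continue
            for allele in range(config.ploidy):
                s = sites.loc[(nid, allele)]
                rows.append({
                    "frame": k, "t_s": float(t), "nucleus_id": nid,
                    "allele": allele, "x_um": s.x_um, "y_um": s.y_um,
                    "z_um": s.z_um, "volume_um3": v,
                })
    return pd.DataFrame(rows)


def simulate_truth(config: SimConfig) -> GroundTruth:
    """Convenience: :func:`build_lineage` followed by :func:`assign_expression`."""
    return assign_expression(build_lineage(config), config)
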