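"""Synthetic herds on synthetic terrain with known ground truth.

Every downstream stage of the package (trajectory cleaning, DEM annotation,
behaviour metrics, mixed-model association) is exercised against data from
this module, because the movement of each simulated cow is generated from
known latent parameters.

The movement model is a correlated random walk with a home-point attraction:

    heading_t = heading_{t-1} + eps_t,          eps_t ~ N(0, 1/kappa)
    cand_t    = pos_{t-1} + L_t * u(heading_t) + uphill drift
    pos_t     = home + (cand_t - home) / (1 + a)

with wrapped-normal turning angles (concentration ``kappa``), gamma step
lengths ``L_t`` (mean = step_scale), and attraction strength ``a >= 0``.  The
position process is an Ornstein-Uhlenbeck-like walk whose stationary spread
shrinks as ``a`` grows, so expected daily home range is monotone decreasing
in attraction while daily distance stays roughly constant -- which produces
the home-range versus tortuosity trade-off the analysis is built to detect.
Genotype and age class act multiplicatively on attraction and turning
concentration (see :class:`grazekit.config.EffectConfig`).

Randomness: one global seed; each cow's stream is derived from the CRC-32 of
its id, so adding or removing a cow never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
import pandas as pd

from .config import AGE_CLASSES, GENOTYPES, SimulationConfig
from .terrain import DemGrid, compute_slope_aspect

_DEM_STREAM = 101
_HERD_STREAM = 202
_TRAJ_STREAM = 303
_MOB_STREAM = 404


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass
class GroundTruth:
    """Latent parameters actually used for each cow, for recovery tests."""

    cows: pd.DataFrame            # per-cow latent movement parameters
    genotype_expect: pd.DataFrame  # per-genotype expected log HR / log tortuosity
    outlier_count: int = 0

    def realized_effects(self) -> pd.DataFrame:
        """Per-genotype expected effects relative to genotype CC."""
        base = self.genotype_expect.set_index("genotype")
        ref = base.loc["CC"]
        out = base - ref
        return out.reset_index()


# ---------------------------------------------------------------------------
# DEM
# ---------------------------------------------------------------------------

def generate_dem(config: SimulationConfig) -> DemGrid:
    """Smooth pseudo-random elevation field from spectrally filtered noise.

    White Gaussian noise is low-pass filtered in the frequency domain with a
    Gaussian kernel of width ``terrain.smoothness`` cells, then rescaled so
    that max - min equals ``terrain.relief``.  Deterministic given the seed.
    """
    t = config.terrain
    if t.n_rows <= 0 or t.n_cols <= 0 or t.cell <= 0:
        raise ValueError("terrain dimensions must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _DEM_STREAM]))
    noise = rng.standard_normal((t.n_rows, t.n_cols))
    if t.relief == 0:
        return DemGrid(xll=0.0, yll=0.0, cell=t.cell,
                       elev=np.zeros((t.n_rows, t.n_cols)))
    ky = np.fft.fftfreq(t.n_rows)[:, None]
    kx = np.fft.fftfreq(t.n_cols)[None, :]
    # Gaussian low-pass; smoothness = correlation length in cells
    filt = np.exp(-2.0 * (np.pi * t.smoothness) ** 2 * (kx**2 + ky**2))
    z = np.fft.ifft2(np.fft.fft2(noise) * filt).real
    z -= z.min()
    z *= t.relief / z.max()
    return DemGrid(xll=0.0, yll=0.0, cell=t.cell, elev=z)


# ---------------------------------------------------------------------------
# herd structure
# ---------------------------------------------------------------------------

def largest_remainder_counts(freqs: dict, n: int) -> dict:
    """Integer counts summing to n whose proportions best match freqs."""
    keys = list(freqs)
    raw = np.array([freqs[k] for k in keys]) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for j in order[:short]:
        base[j] += 1
    return dict(zip(keys, base.tolist()))


def simulate_herd(config: SimulationConfig) -> pd.DataFrame:
    """Cow metadata: id, genotype, age class, farm, mob, sire, year.

    Mobs are assigned round-robin to farm x year cells.  Genotypes come from
    ``genotype_freqs`` either per-cow multinomially or, in ``expected`` mode,
    as deterministic largest-remainder counts shuffled across cows.  Each mob
    draws at least two sires from a farm-level pool, so sires are partially
    shared between mobs of a farm.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _HERD_STREAM]))
    n_cows = config.n_mobs * config.cows_per_mob
    cells = [(f, y) for f in range(1, config.n_farms + 1)
             for y in range(2019, 2019 + config.n_years)]
    rows = []
    # farm-level sire pools, ~1 sire per 4 cows on a farm
    mobs_per_farm: dict[int, int] = {}
    for m in range(config.n_mobs):
        farm, _ = cells[m % len(cells)]
        mobs_per_farm[farm] = mobs_per_farm.get(farm, 0) + 1
    sire_pool = {
        farm: [f"S{farm}{i:02d}" for i in range(1, max(3, cnt * config.cows_per_mob // 4) + 1)]
        for farm, cnt in mobs_per_farm.items()
    }
    cow_no = 0
    for m in range(config.n_mobs):
        farm, year = cells[m % len(cells)]
        mob_id = f"M{m + 1:02d}"
        n_sires = max(2, config.cows_per_mob // 4)
        sires = rng.choice(sire_pool[farm], size=min(n_sires, len(sire_pool[farm])),
                           replace=False)
        for _ in range(config.cows_per_mob):
            cow_no += 1
            rows.append({
                "cow_id": f"C{cow_no:04d}",
                "farm": farm,
                "year": year,
                "mob": mob_id,
                "sire": str(rng.choice(sires)),
            })
    meta = pd.DataFrame(rows)
    geno_keys = [g for g in GENOTYPES if config.genotype_freqs.get(g, 0) > 0]
    freqs = {g: config.genotype_freqs[g] for g in geno_keys}
    if config.genotype_mode == "expected":
        counts = largest_remainder_counts(freqs, n_cows)
        geno = np.repeat(list(counts.keys()), list(counts.values()))
        rng.shuffle(geno)
    else:
        p = np.array(list(freqs.values()))
        geno = rng.choice(list(freqs.keys()), size=n_cows, p=p / p.sum())
    meta["genotype"] = geno
    ages = [a for a in AGE_CLASSES if config.age_class_freqs.get(a, 0) > 0]
    pa = np.array([config.age_class_freqs[a] for a in ages], dtype=float)
    meta["age_class"] = rng.choice(ages, size=n_cows, p=pa / pa.sum())
    return meta


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def cow_movement_params(config: SimulationConfig, genotype: str, age_class: int):
    """(step_scale, kappa, attraction, elevation_pref) for a genotype x age cell."""
    mv = config.movement
    ef = config.effects
    attraction = mv.attraction
    kappa = mv.turn_concentration
    if "A" in genotype:
        attraction *= ef.attraction_mult_A
        kappa *= ef.turn_conc_mult_A
    if "B" in genotype:
        attraction *= ef.attraction_mult_B
        kappa *= ef.turn_conc_mult_B
    attraction *= ef.age_attraction_mult.get(int(age_class), 1.0)
    return mv.step_scale, kappa, attraction, mv.elevation_pref


def expected_log_metrics(config: SimulationConfig, genotype: str, age_class: int = 2):
    """Analytic proxies for expected log home range (ha) and log tortuosity.

    Under an uncorrelated-step approximation the stationary per-coordinate
    variance of the walk is sigma_step^2 / (1 - phi^2) with phi = 1/(1 + a);
    home range scales with that variance, and daily distance is cadence *
    step_scale, so log tortuosity is log(distance) - log(area).  These are
    order-of-magnitude proxies used for monotonicity ground truth, not
    calibrated predictions.
    """
    step_scale, kappa, a, _ = cow_movement_params(config, genotype, age_class)
    phi = 1.0 / (1.0 + a)
    sigma_step2 = (step_scale**2) / 2.0  # per coordinate, E[L^2]/2 up to shape
    sigma_stat2 = sigma_step2 / max(1.0 - phi**2, 1e-12)
    n_per_day = 86400 // config.fix_interval
    log_hr = float(np.log(np.pi * 4.0 * sigma_stat2 / 1e4))  # ~95% ellipse, ha
    log_dist = float(np.log(n_per_day * step_scale))
    return log_hr, log_dist - log_hr


def _cow_rng(seed: int, cow_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, _TRAJ_STREAM, zlib.crc32(cow_id.encode())])
    )


def simulate_trajectories(
    metadata: pd.DataFrame,
    dem: DemGrid,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate 5-min GPS fixes for every cow in ``metadata``.

    Returns ``(fixes, ground_truth)``.  The fix table has columns ``cow_id``,
    ``timestamp`` (UTC), ``x``, ``y`` and ``is_outlier`` (True for injected
    teleport fixes; the column is in-memory only and not written to CSV).
    Fixes are dropped independently at ``dropout_rate``.
    """
    if dem.slope_deg is None:
        compute_slope_aspect(dem)
    xmin, ymin, xmax, ymax = dem.extent
    mx = 0.15 * (xmax - xmin)
    my = 0.15 * (ymax - ymin)
    n_steps = config.days * 86400 // config.fix_interval
    t0 = pd.Timestamp(config.start)
    times = t0 + pd.to_timedelta(np.arange(n_steps) * config.fix_interval, unit="s")

    # mob home centres on a jittered grid over the DEM interior
    mobs = sorted(metadata["mob"].unique())
    mob_rng = np.random.default_rng(np.random.SeedSequence([config.seed, _MOB_STREAM]))
    k = int(np.ceil(np.sqrt(len(mobs))))
    gx = np.linspace(xmin + mx, xmax - mx, k)
    gy = np.linspace(ymin + my, ymax - my, k)
    centres = [(gx[i % k], gy[i // k]) for i in range(len(mobs))]
    centres = [(cx + mob_rng.normal(0, mx * 0.05), cy + mob_rng.normal(0, my * 0.05))
               for cx, cy in centres]
    mob_centre = dict(zip(mobs, centres))

    # uphill unit gradient grids for the elevation preference term
    grad = np.radians(dem.slope_deg)
    gup_len = np.tan(grad)
    az = np.radians(dem.aspect_deg)  # downslope azimuth from north
    with np.errstate(invalid="ignore"):
        ux = np.where(np.isnan(az), 0.0, -np.sin(az))  # uphill = -downhill
        uy = np.where(np.isnan(az), 0.0, -np.cos(az))
    strength = np.clip(gup_len, 0.0, 1.0)
    ux *= strength
    uy *= strength

    frames = []
    gt_rows = []
    n_outliers_total = 0
    for mob_id, sub in metadata.groupby("mob", sort=True):
        cows = sub["cow_id"].to_numpy()
        nc = len(cows)
        cx, cy = mob_centre[mob_id]
        if not (xmin + mx / 2 <= cx <= xmax - mx / 2 and ymin + my / 2 <= cy <= ymax - my / 2):
            raise SimulationError(f"mob {mob_id} home centre outside DEM bounds")
        step_l = np.empty((nc, n_steps))
        turns = np.empty((nc, n_steps))
        keep = np.ones((nc, n_steps), dtype=bool)
        outlier = np.zeros((nc, n_steps), dtype=bool)
        homes = np.empty((nc, 2))
        attraction = np.empty(nc)
        elev_pref = np.empty(nc)
        h0 = np.empty(nc)
        for i, row in enumerate(sub.itertuples()):
            rng = _cow_rng(config.seed, row.cow_id)
            s, kappa, a, ep = cow_movement_params(config, row.genotype, row.age_class)
            homes[i] = (
                np.clip(cx + rng.normal(0, config.home_scatter),
                        xmin + mx / 2, xmax - mx / 2),
                np.clip(cy + rng.normal(0, config.home_scatter),
                        ymin + my / 2, ymax - my / 2),
            )
            if not dem.contains(homes[i, 0], homes[i, 1]):
                raise SimulationError(f"cow {row.cow_id} home point outside DEM bounds")
            attraction[i] = a
            elev_pref[i] = ep
            h0[i] = rng.uniform(-np.pi, np.pi)
            step_l[i] = rng.gamma(2.0, s / 2.0, size=n_steps)
            turns[i] = rng.normal(0.0, 1.0 / np.sqrt(kappa), size=n_steps)
            if config.dropout_rate > 0:
                if config.bursty_dropout:
                    keep[i] = _bursty_keep(rng, n_steps, config.dropout_rate)
                else:
                    keep[i] = rng.random(n_steps) >= config.dropout_rate
            if config.outlier_rate > 0:
                cand = rng.random(n_steps) < config.outlier_rate
                cand[:2] = cand[-2:] = False
                # keep spikes isolated so each has a clean return step
                idx = np.flatnonzero(cand)
                sel = []
                last = -10
                for j in idx:
                    if j - last > 2:
                        sel.append(j)
                        last = j
                outlier[i, sel] = True
            gt_rows.append({
                "cow_id": row.cow_id, "mob": mob_id, "genotype": row.genotype,
                "age_class": row.age_class, "home_x": homes[i, 0], "home_y": homes[i, 1],
                "step_scale": s, "turn_concentration": kappa, "attraction": a,
                "elevation_pref": ep,
            })
        # vectorised recursion over time
        pos = homes.copy()
        heading = h0.copy()
        shrink = 1.0 / (1.0 + attraction)
        xs = np.empty((nc, n_steps))
        ys = np.empty((nc, n_steps))
        for tstep in range(n_steps):
            heading = heading + turns[:, tstep]
            r, c = dem.index_of(pos[:, 0], pos[:, 1])
            bias = elev_pref[:, None] * step_l[:, tstep, None] * np.stack(
                [ux[r, c], uy[r, c]], axis=1)
            cand = pos + step_l[:, tstep, None] * np.stack(
                [np.cos(heading), np.sin(heading)], axis=1) + bias
            pos = homes + (cand - homes) * shrink[:, None]
            np.clip(pos[:, 0], xmin + 1.0, xmax - 1.0, out=pos[:, 0])
            np.clip(pos[:, 1], ymin + 1.0, ymax - 1.0, out=pos[:, 1])
            xs[:, tstep] = pos[:, 0]
            ys[:, tstep] = pos[:, 1]
        # inject teleport spikes after the walk so the path returns next fix
        if config.outlier_rate > 0:
            disp = config.outlier_speed_factor * 2.5 * config.fix_interval
            for i in range(nc):
                idx = np.flatnonzero(outlier[i])
                if len(idx):
                    rng = _cow_rng(config.seed, cows[i] + "-spike")
                    ang = rng.uniform(-np.pi, np.pi, size=len(idx))
                    xs[i, idx] += disp * np.cos(ang)
                    ys[i, idx] += disp * np.sin(ang)
                    n_outliers_total += len(idx)
        for i, cow_id in enumerate(cows):
            m = keep[i]
            frames.append(pd.DataFrame({
                "cow_id": cow_id,
                "timestamp": times[m],
                "x": xs[i, m],
                "y": ys[i, m],
                "is_outlier": outlier[i, m],
            }))
    fixes = pd.concat(frames, ignore_index=True)
    gt_cows = pd.DataFrame(gt_rows)
    exp_rows = []
    for g in sorted(metadata["genotype"].unique()):
        lh, lt = expected_log_metrics(config, g)
        exp_rows.append({"genotype": g, "expected_log_hr": lh, "expected_log_tortuosity": lt})
    gt = GroundTruth(cows=gt_cows, genotype_expect=pd.DataFrame(exp_rows),
                     outlier_count=n_outliers_total)
    return fixes, gt


def _bursty_keep(rng: np.random.Generator, n: int, rate: float,
                 mean_burst: float = 6.0) -> np.ndarray:
    """Two-state Markov dropout with the requested marginal rate."""
    p_exit = 1.0 / mean_burst                     # leave the dropped state
    p_enter = rate * p_exit / max(1.0 - rate, 1e-9)
    keep = np.ones(n, dtype=bool)
    dropped = False
    u = rng.random(n)
    for i in range(n):
        dropped = (u[i] >= p_exit) if dropped else (u[i] < p_enter)
        keep[i] = not dropped
    return keep


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fixes(fixes: pd.DataFrame, path) -> None:
    out = fixes[["cow_id", "timestamp", "x", "y"]].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.3f")


def write_ground_truth(gt: GroundTruth, cows_path, genotype_path) -> None:
    gt.cows.to_csv(cows_path, index=False)
    gt.genotype_expect.to_csv(genotype_path, index=False)
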