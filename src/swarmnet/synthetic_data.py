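"""Synthetic observation-window datasets with known generating structure.

The generator emulates the study design the analysis assumes: seven
sites spanning a rainfall gradient (2103–2862 mm/yr) and a habitat
suitability gradient (0.31–0.99); 1–27 swarm-days per site, with a
swarm followed for up to three consecutive days; 2–6 five-minute
windows per swarm-day; and a regional pool of ~110 species whose site
occupancy decays with rainfall distance, so most species occur at only
one or two sites (high among-site turnover).

Two site-level linear predictors drive network structure, both on the
observation-level standardized (z) scale that the fitted models use:

* size model      log λ = β0 + βR·zR + βH·zH   (swarm-day richness,
  Poisson; defaults β0 = 2.065, βR = −0.176, βH = 0.093)
* cohesion model  logit q = γ0 + γR·zR + γH·zH  (per-species,
  per-window attendance probability, which jointly drives weighted
  degree, clustering, and skewness)

Every random draw flows from one seed; identical seeds give identical
datasets byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import special

from .errors import ValidationError
from .habitat_suitability import NdviRaster, buffer_cells
from .obs_io import ObservationWindow, SiteEnvironment, write_site_env, write_windows

BASE_DATE = _dt.date(2021, 3, 1)


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters; defaults are the emulated study conditions."""

    n_sites: int = 7
    rainfall_range: tuple[float, float] = (2103.0, 2862.0)
    suitability_range: tuple[float, float] = (0.31, 0.99)
    days_per_site: tuple[int, int] = (1, 27)
    windows_per_swarm: tuple[int, int] = (2, 6)
    window_probs: tuple[tuple[int, float], ...] | None = None  # e.g. ((3,.73),(4,.20),(2,.07))
    pool_size: int = 110
    turnover_decay: float = 2.0  # occupancy ~ exp(-decay * (z-rainfall distance)^2)
    niche_margin: float = 0.3  # niche centers drawn this far beyond the z-range
    size_beta0: float = 2.065
    size_beta_rain: float = -0.176
    size_beta_suit: float = 0.093
    coh_gamma0: float = 1.0
    coh_gamma_rain: float = 0.3
    coh_gamma_suit: float = 0.3
    max_days_per_swarm: int = 3
    abundance_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 2:
            raise ValidationError("need >= 2 sites")
        for name in ("rainfall_range", "suitability_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be non-degenerate")
        if self.turnover_decay < 0:
            raise ValidationError("turnover_decay must be >= 0")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")


@dataclass
class SimTruth:
    """Everything needed to score recovery of the fitted coefficients."""

    config: SimConfig
    site_table: list[dict]
    pools: dict[str, list[str]]
    row_table: list[dict] = field(default_factory=list)  # one row per swarm-day
    n_birdless: int = 0
    n_truncated: int = 0

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "sites": self.site_table,
            "pools": self.pools,
            "swarm_days": self.row_table,
            "n_birdless": self.n_birdless,
            "n_truncated": self.n_truncated,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _species_codes(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(1, n + 1)]


def simulate_sites(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[SiteEnvironment], dict[str, list[str]]]:
    """Draw site environments and per-site species pools.

    Rainfall and suitability each span their configured range (the two
    extremes are pinned to the endpoints; suitability order is shuffled
    so the gradients are not collinear).  Each species has a rainfall
    niche center; occupancy probability decays with squared z-rainfall
    distance, producing high among-site turnover at the default decay.
    """
    cfg.validate()
    n = cfg.n_sites
    r_lo, r_hi = cfg.rainfall_range
    s_lo, s_hi = cfg.suitability_range
    rain = np.sort(np.r_[r_lo, rng.uniform(r_lo, r_hi, n - 2), r_hi])
    suit = rng.permutation(np.r_[s_lo, rng.uniform(s_lo, s_hi, n - 2), s_hi])
    sites = [
        SiteEnvironment(f"S{i+1}", float(rain[i]), float(round(suit[i], 4)))
        for i in range(n)
    ]

    zr = (rain - rain.mean()) / rain.std()
    centers = rng.uniform(zr.min() - cfg.niche_margin, zr.max() + cfg.niche_margin,
                          cfg.pool_size)
    p_occ = np.exp(-cfg.turnover_decay * (zr[None, :] - centers[:, None]) ** 2)
    occ = rng.random((cfg.pool_size, n)) < p_occ
    codes = _species_codes(cfg.pool_size)
    pools = {
        site.site_id: [codes[s] for s in range(cfg.pool_size) if occ[s, i]]
        for i, site in enumerate(sites)
    }
    return sites, pools


def occupancy_summary(pools: dict[str, list[str]]) -> dict[str, float]:
    """Fraction of occurring species found at <= 2 sites, plus counts."""
    counts: dict[str, int] = {}
    for members in pools.values():
        for sp in members:
            counts[sp] = counts.get(sp, 0) + 1
    n_occ = len(counts)
    if n_occ == 0:
        return {"n_species": 0, "frac_le2_sites": float("nan")}
    le2 = sum(1 for v in counts.values() if v <= 2)
    return {"n_species": n_occ, "frac_le2_sites": le2 / n_occ}


def _window_counts(cfg: SimConfig, size: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.window_probs is not None:
        vals = np.array([v for v, _ in cfg.window_probs])
        probs = np.array([p for _, p in cfg.window_probs], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(vals, size=size, p=probs)
    lo, hi = cfg.windows_per_swarm
    return rng.integers(lo, hi + 1, size=size)


def simulate_swarms(
    cfg: SimConfig,
    sites: list[SiteEnvironment],
    pools: dict[str, list[str]],
    rng: np.random.Generator,
) -> tuple[list[ObservationWindow], SimTruth]:
    """Simulate observation windows for every swarm-day.

    Swarm-day richness is Poisson in the size model (truncated at the
    site pool); each attending species is independently present in each
    window with the cohesion probability q, conditioned on appearing in
    at least one window.  Windows left with zero species are dropped;
    swarm-days with zero richness are birdless and emit no windows.
    """
    # Allocate swarm-days first so z-scores are on the observation scale.
    rows: list[tuple[SiteEnvironment, str, _dt.date]] = []
    for site in sites:
        n_days = int(rng.integers(cfg.days_per_site[0], cfg.days_per_site[1] + 1))
        day_cursor = 0
        swarm_idx = 0
        remaining = n_days
        while remaining > 0:
            dur = int(min(rng.integers(1, cfg.max_days_per_swarm + 1), remaining))
            swarm_idx += 1
            swarm_id = f"{site.site_id}-sw{swarm_idx:03d}"
            for d in range(dur):
                rows.append((site, swarm_id, BASE_DATE + _dt.timedelta(days=day_cursor + d)))
            day_cursor += dur + int(rng.integers(1, 10))
            remaining -= dur

    rain = np.array([s.rainfall for s, _, _ in rows])
    suit = np.array([s.suitability for s, _, _ in rows])
    zr = (rain - rain.mean()) / rain.std(ddof=1)
    zh = (suit - suit.mean()) / suit.std(ddof=1)
    lam = np.exp(cfg.size_beta0 + cfg.size_beta_rain * zr + cfg.size_beta_suit * zh)
    q = special.expit(cfg.coh_gamma0 + cfg.coh_gamma_rain * zr + cfg.coh_gamma_suit * zh)
    n_wins = _window_counts(cfg, len(rows), rng)

    truth = SimTruth(
        config=cfg,
        site_table=[asdict(s) for s in sites],
        pools={k: list(v) for k, v in pools.items()},
    )
    # Regional abundance is a persistent species trait: common species
    # attend many swarms (the field pattern), rare ones only a few.
    abundance = {
        code: float(a)
        for code, a in zip(
            _species_codes(cfg.pool_size),
            rng.lognormal(0.0, cfg.abundance_sd, cfg.pool_size),
        )
    }
    windows: list[ObservationWindow] = []
    for i, (site, swarm_id, date) in enumerate(rows):
        pool = pools[site.site_id]
        richness = int(rng.poisson(lam[i]))
        if richness > len(pool):
            richness = len(pool)
            truth.n_truncated += 1
        record = {
            "site_id": site.site_id,
            "swarm_id": swarm_id,
            "date": date.isoformat(),
            "richness": richness,
            "lambda": float(lam[i]),
            "q": float(q[i]),
            "z_rainfall": float(zr[i]),
            "z_suitability": float(zh[i]),
            "n_windows_drawn": int(n_wins[i]),
        }
        truth.row_table.append(record)
        if richness == 0:
            truth.n_birdless += 1
            continue
        weights = np.array([abundance[sp] for sp in pool])
        weights /= weights.sum()
        chosen = rng.choice(len(pool), size=richness, replace=False, p=weights)
        species = [pool[j] for j in chosen]
        nw = int(n_wins[i])
        present = rng.random((richness, nw)) < q[i]
        for s_idx in np.where(~present.any(axis=1))[0]:
            present[s_idx, rng.integers(nw)] = True  # condition on >=1 window
        for w_idx in range(nw):
            members = frozenset(
                species[s_idx] for s_idx in np.where(present[:, w_idx])[0]
            )
            if not members:
                continue  # window with zero species is dropped
            windows.append(
                ObservationWindow(
                    site_id=site.site_id,
                    swarm_id=swarm_id,
                    date=date,
                    window_index=w_idx + 1,
                    species=members,
                )
            )
    return windows, truth


def simulate_dataset(
    cfg: SimConfig | None = None, seed: int | None = None
) -> tuple[list[SiteEnvironment], list[ObservationWindow], SimTruth]:
    """Sites + windows + truth in one call (seed overrides cfg.seed)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sites, pools = simulate_sites(cfg, rng)
    windows, truth = simulate_swarms(cfg, sites, pools, rng)
    return sites, windows, truth


def write_dataset(
    out_dir: str | Path,
    sites: list[SiteEnvironment],
    windows: list[ObservationWindow],
    truth: SimTruth,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "windows": out / "windows.csv",
        "sites": out / "sites.csv",
        "truth": out / "truth.json",
    }
    write_windows(windows, paths["windows"])
    write_site_env({s.site_id: s for s in sites}, paths["sites"])
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths


# ---------------------------------------------------------------------------
# Constructed rasters with known suitability

@dataclass(frozen=True)
class RasterTruth:
    target: float
    n_buffer_cells: int
    n_matched: int

    @property
    def realized(self) -> float:
        return self.n_matched / self.n_buffer_cells


def simulate_raster(
    target: float,
    *,
    shape: tuple[int, int] = (40, 40),
    fragment_halfwidth: int = 6,
    cell_size: float = 30.0,
    distance: float = 200.0,
    forest_ndvi: float = 0.8,
    matrix_ndvi: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[NdviRaster, np.ndarray, RasterTruth]:
    """Construct a raster whose suitability is exactly ``target``.

    A square fragment of constant forest NDVI sits mid-grid, so its
    percentile envelope collapses to a point; buffer cells are then set
    in- or out-of-envelope by direct count.  When the buffer size is
    not divisible by the target's denominator, a few buffer cells are
    masked so that the realized proportion equals the target exactly.
    """
    if not 0.0 <= target <= 1.0:
        raise ValidationError("target suitability must be in [0, 1]")
    nr, nc = shape
    fragment = np.zeros(shape, dtype=bool)
    r0, c0 = nr // 2, nc // 2
    hw = fragment_halfwidth
    fragment[r0 - hw : r0 + hw, c0 - hw : c0 + hw] = True

    values = np.full(shape, matrix_ndvi, dtype=float)
    values[fragment] = forest_ndvi
    buf = buffer_cells(fragment, distance=distance, cell_size=cell_size)
    idx = np.argwhere(buf)

    frac = Fraction(target).limit_denominator(10_000)
    n = len(idx)
    mask = np.zeros(shape, dtype=bool)
    drop = n % frac.denominator if frac.denominator > 1 else 0
    for r, c in idx[:drop]:
        mask[r, c] = True
    usable = idx[drop:]
    n_use = len(usable)
    k = int(round(target * n_use))
    order = (
        rng.permutation(n_use) if rng is not None else np.arange(n_use)
    )
    for r, c in usable[order[:k]]:
        values[r, c] = forest_ndvi
    raster = NdviRaster(values=values, cell_size=cell_size, mask=mask)
    return raster, fragment, RasterTruth(target=target, n_buffer_cells=n_use, n_matched=k)
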