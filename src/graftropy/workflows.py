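"""Experiment orchestration: configs, seed discipline, fixtures, exports.

A run is described by a flat, human-editable configuration (``key: value``
lines, no nesting).  All randomness flows from one master seed through
named substreams (surface, anchors, chains, replicates) so that any stage
can be re-run independently and results are byte-reproducible.  Every
results file embeds a hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .entropy import EntropyProfile, anchoring_entropy, estimate_profile
from .fits import fit_log_slope, fit_power_law
from .lattice import LatticeConfig
from .roughness import characterize
from .sampling import (
    EnsembleStats,
    anchored_environment,
    free_environment,
    random_anchor_environment,
    sample_ensemble,
)
from .surfaces import (
    HeightField,
    generate_rmd,
    generate_ugm,
    select_anchor,
)

#: Named substreams of the master seed (counter-based fan-out).
SEED_STREAMS = {"surface": 1, "anchor": 2, "chains": 3, "replicates": 4}


def derive_seed(master_seed: int, stream: str, index: int = 0) -> int:
    """Derive an independent 31-bit seed for a named substream.

    Uses :class:`numpy.random.SeedSequence` with the (stream id, index)
    spawn key, so substreams never collide and runs are reproducible.
    """
    if stream not in SEED_STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}")
    ss = np.random.SeedSequence(master_seed, spawn_key=(SEED_STREAMS[stream], index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Parameters of one simulation experiment."""

    surface_type: str = "flat"  # flat | ugm | bm | fbm
    L: int = 1024
    z0: int = 300
    sigma: float = 1.0
    hurst: float = 0.5
    anchor_mode: Optional[str] = None  # None => free chains only
    n_list: tuple[int, ...] = (10, 22, 46, 100)
    n_samples: int = 1000
    seed: int = 0
    weighting: str = "rosenbluth"
    fit_nmin: float = 10.0
    fit_nmax: float = 100.0
    box_edge: int = 601

    def to_text(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key}: {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            raw[key.strip()] = value.strip()
        kwargs = {}
        for name, f in cls.__dataclass_fields__.items():
            if name not in raw:
                continue
            text_val = raw[name]
            if name == "n_list":
                kwargs[name] = tuple(int(v) for v in text_val.split(","))
            elif name == "anchor_mode":
                kwargs[name] = None if text_val in ("", "None", "none") else text_val
            elif f.type in ("int",):
                kwargs[name] = int(text_val)
            elif f.type in ("float",):
                kwargs[name] = float(text_val)
            else:
                kwargs[name] = text_val
        return cls(**kwargs)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def make_fixture(name: str, size: int = 5, seed: int = 0, z0: int = 0) -> HeightField:
    """Small deterministic heightfields for oracle checks.

    ``flat``: constant altitude; ``bump``: one centre cell raised by 1;
    ``wedge``: linear ramp along x; ``staircase``: ramp quantized in steps
    of 2; ``tiny_ugm``: seeded uncorrelated Gaussian surface.
    """
    if size < 5:
        raise ValueError(f"fixture size must be >= 5, got {size}")
    if name == "flat":
        z = np.full((size, size), z0, dtype=np.int32)
    elif name == "bump":
        z = np.full((size, size), z0, dtype=np.int32)
        z[size // 2, size // 2] += 1
    elif name == "wedge":
        z = np.tile(np.arange(size, dtype=np.int32), (size, 1)).T + z0
    elif name == "staircase":
        z = (np.tile(np.arange(size, dtype=np.int32), (size, 1)).T // 2) * 2 + z0
    elif name == "tiny_ugm":
        return generate_ugm(size, z0=z0, sigma=1.0, seed=seed)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return HeightField(z=z, L=size, meta={"type": name, "L": size, "z0": z0, "seed": seed})


def build_surface(config: RunConfig) -> Optional[HeightField]:
    """Generate the parent surface of a run (None for free chains)."""
    seed = derive_seed(config.seed, "surface")
    if config.surface_type == "flat":
        return HeightField(
            z=np.full((config.L, config.L), config.z0, dtype=np.int32),
            L=config.L,
            meta={"type": "flat", "L": config.L, "z0": config.z0},
        )
    if config.surface_type == "ugm":
        return generate_ugm(config.L, config.z0, config.sigma, seed)
    if config.surface_type in ("bm", "fbm"):
        hurst = 0.5 if config.surface_type == "bm" else config.hurst
        return generate_rmd(config.L, config.z0, hurst, config.sigma, seed)
    raise ValueError(f"unknown surface type {config.surface_type!r}")


def build_environment(config: RunConfig, parent: Optional[HeightField]):
    lattice = LatticeConfig(box_edge=config.box_edge)
    if config.anchor_mode is None:
        return free_environment(lattice)
    if parent is None:
        raise ValueError("anchored run needs a surface")
    if config.anchor_mode == "random":
        return random_anchor_environment(parent, lattice)
    anchor = select_anchor(parent, config.anchor_mode, derive_seed(config.seed, "anchor"))
    return anchored_environment(parent, anchor, lattice)


def profile_frame(profile: EntropyProfile) -> pd.DataFrame:
    """Per-step results table: (i, omega_eff, cum_S_over_kB)."""
    steps = np.arange(1, len(profile.omega_eff) + 1)
    return pd.DataFrame(
        {"i": steps, "omega_eff": profile.omega_eff, "cum_S_over_kB": profile.cum_S}
    )


def chains_to_xyz(stats: EnsembleStats, path: str | Path, limit: int = 10) -> None:
    """Export up to ``limit`` chain trajectories in XYZ-style text."""
    if stats.sites is None:
        raise ValueError("ensemble was sampled without site storage")
    path = Path(path)
    with path.open("w") as fh:
        for r in range(min(limit, stats.sites.shape[0])):
            sites = stats.sites[r]
            fh.write(f"{len(sites)}\nchain {r}\n")
            for x, y, z in sites:
                fh.write(f"C {int(x)} {int(y)} {int(z)}\n")


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute one experiment end to end.

    Pipeline: surface generation → roughness characterization → ensemble
    sampling over the configured chain lengths → entropy profiles → (for
    anchored runs) anchoring entropies and scaling fits.  Writes CSV/JSON
    artifacts when ``out_dir`` is given and returns the results bundle.
    """
    t_start = time.time()
    parent = build_surface(config)
    bundle: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "version": __version__,
    }
    if parent is not None and parent.L >= 2:
        rep = characterize(parent)
        bundle["surface"] = {
            "D_F": rep.D_F,
            "sigma_emp": rep.sigma_emp,
            "area_total": rep.area_total,
            "L": rep.L,
        }
    env = build_environment(config, parent)
    free_env = free_environment(LatticeConfig(box_edge=config.box_edge))

    rows = []
    per_n = {}
    for idx, n in enumerate(config.n_list):
        seed_n = derive_seed(config.seed, "chains", idx)
        stats = sample_ensemble(env, int(n), config.n_samples, seed_n)
        profile = estimate_profile(stats, config.weighting)
        entry = {
            "N": int(n),
            "S_over_kB": profile.S,
            "n_dead": stats.n_dead,
            "n_samples": config.n_samples,
        }
        if config.anchor_mode is not None:
            free_stats = sample_ensemble(
                free_env, int(n), config.n_samples, derive_seed(config.seed, "chains", 1000 + idx)
            )
            free_profile = estimate_profile(free_stats, config.weighting)
            entry["S_free_over_kB"] = free_profile.S
            entry["delta_S_over_kB"] = anchoring_entropy(profile, free_profile)
        rows.append(entry)
        per_n[int(n)] = profile
    bundle["entropies"] = rows

    if config.anchor_mode is not None and len(rows) >= 4:
        n_arr = [row["N"] for row in rows]
        ds = [row["delta_S_over_kB"] for row in rows]
        costs = [-v for v in ds]
        fit_range = (config.fit_nmin, config.fit_nmax)
        if all(c > 0 for c in costs):
            pw = fit_power_law(n_arr, costs, fit_range=fit_range)
            bundle["power_law_fit"] = {
                "A": pw.A,
                "zeta": pw.zeta,
                "r_squared": pw.r_squared,
                "fit_range": list(pw.fit_range),
            }
        ls = fit_log_slope(n_arr, ds, fit_range=fit_range)
        bundle["log_slope_fit"] = {
            "delta_gamma": ls.delta_gamma,
            "intercept": ls.intercept,
            "r_squared": ls.r_squared,
        }
    bundle["elapsed_s"] = time.time() - t_start

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out_dir / "entropies.csv", index=False)
        for n, profile in per_n.items():
            profile_frame(profile).to_csv(out_dir / f"profile_N{n}.csv", index=False)
        with (out_dir / "summary.json").open("w") as fh:
            json.dump(bundle, fh, indent=2, default=float)
        with (out_dir / "run.log").open("w") as fh:
            fh.write(f"graftropy {__version__} config {config.config_hash}\n")
            for row in rows:
                fh.write(
                    f"N={row['N']} S={row['S_over_kB']:.4f} "
                    f"n_dead={row['n_dead']}/{row['n_samples']}\n"
                )
            fh.write(f"elapsed {bundle['elapsed_s']:.1f} s\n")
    return bundle


def check_same_config(*bundles: dict) -> None:
    """Raise if results bundles come from different configurations."""
    hashes = {b.get("config_hash") for b in bundles}
    if len(hashes) > 1:
        raise ValueError(f"mixing results from different configs: {hashes}")
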