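"""Named reference models and the programmatic fixture generator.

The reference models mirror the canonical single-exponential examples
(stable J = -1, fragile J = 1, divergent J = 3, all with c = 5 1/s and
tau = 20 ms), a dead-time-only model, a homogeneous Poisson model, and a
fixed basis-kernel model with a relative refractory period followed by a
mild rebound. All test inputs are produced by simulating these models; no
external data are required.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np

from . import __version__
from .basis import RaisedCosineBasis
from .io import write_config, write_spike_trains
from .models import (BasisKernel, HawkesModel, RefractorySpec,
                     SingleExpKernel)
from .simulate import SimulationConfig, simulate

__all__ = ["reference_model", "FIXTURE_NAMES", "generate_fixtures",
           "BASIS_BETA"]

#: coefficients of the reference basis-kernel model: early suppression
#: (relative refractoriness) with a mild excitatory rebound, then decay
BASIS_BETA = (-3.0, -1.5, -0.5, 0.4, 0.5, 0.3, 0.1, -0.1, -0.2, -0.1)

FIXTURE_NAMES = ("exp_stable", "exp_fragile", "exp_divergent",
                 "refractory_only", "poisson", "basis_model")


def reference_model(name: str) -> HawkesModel:
    refr = RefractorySpec(tau_ref=0.002)
    if name == "exp_stable":
        return HawkesModel.from_rate(
            5.0, SingleExpKernel(J=-1.0, tau=0.02, refractory=refr))
    if name == "exp_fragile":
        return HawkesModel.from_rate(
            5.0, SingleExpKernel(J=1.0, tau=0.02, refractory=refr))
    if name == "exp_divergent":
        return HawkesModel.from_rate(
            5.0, SingleExpKernel(J=3.0, tau=0.02, refractory=refr))
    if name == "refractory_only":
        return HawkesModel.from_rate(
            5.0, SingleExpKernel(J=0.0, tau=0.02, refractory=refr))
    if name == "poisson":
        return HawkesModel.from_rate(
            5.0, SingleExpKernel(J=0.0, tau=0.02,
                                 refractory=RefractorySpec(tau_ref=0.0)))
    if name == "basis_model":
        return HawkesModel.from_rate(
            10.0, BasisKernel(beta=BASIS_BETA, basis=RaisedCosineBasis(),
                              refractory=refr))
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def generate_fixtures(out_dir, names: Optional[Iterable[str]] = None,
                      seed: int = 0, duration: float = 100.0,
                      n_replicates: int = 2,
                      dt_sim: float = 2e-4) -> Dict[str, dict]:
    """Write model configs, simulated spike trains and a manifest.

    Regeneration with the same seed is bit-identical; the manifest records
    seeds and the library version so the exact models can be re-read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(names) if names is not None else list(FIXTURE_NAMES)
    manifest: Dict[str, dict] = {}
    for i, name in enumerate(names):
        model = reference_model(name)
        cfg_path = out / f"{name}.cfg"
        write_config(cfg_path, model)
        fixture_seed = int(np.random.SeedSequence([seed, i]).generate_state(
            1, dtype=np.uint32)[0] % (2 ** 31))
        config = SimulationConfig(dt_sim=dt_sim, duration=duration,
                                  n_replicates=n_replicates,
                                  seed=fixture_seed,
                                  stop_on_divergence=True)
        trains = simulate(model, config)
        spk_path = out / f"{name}_spikes.txt"
        write_spike_trains(spk_path, trains)
        manifest[name] = {
            "config": cfg_path.name,
            "spikes": spk_path.name,
            "seed": fixture_seed,
            "duration": duration,
            "n_replicates": n_replicates,
            "dt_sim": dt_sim,
        }
    payload = {"version": __version__, "master_seed": seed,
               "fixtures": manifest}
    (out / "manifest.json").write_text(json.dumps(payload, indent=2))
    return manifest
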