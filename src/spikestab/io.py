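"""Plain-text I/O: model config files and spike-train files.

Config files are flat ``key = value`` text (comments with ``#``); spike
trains are one spike time (s) per line at 9 significant digits, with blank
lines separating trials in multi-trial files. An optional
``# duration = <T>`` comment per trial preserves the trial length through a
round trip; files without it fall back to the last spike time rounded up.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np

from .basis import RaisedCosineBasis
from .models import (BasisKernel, DoubleExpKernel, HawkesModel, Nonlinearity,
                     RefractorySpec, SingleExpKernel, SpikeTrain)
from .stability import StabilityReport

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "model_to_config",
    "model_from_config",
    "write_config",
    "read_config",
    "report_to_dict",
]

PathLike = Union[str, Path]


def write_spike_trains(path: PathLike,
                       trains: Sequence[SpikeTrain]) -> None:
    lines: List[str] = []
    for i, tr in enumerate(trains):
        if i:
            lines.append("")
        lines.append(f"# duration = {tr.duration!r}")
        lines.extend(f"{t:.9g}" for t in tr.times)
    Path(path).write_text("\n".join(lines) + "\n")


def read_spike_trains(path: PathLike) -> List[SpikeTrain]:
    trains: List[SpikeTrain] = []
    times: List[float] = []
    duration = None

    def flush() -> None:
        nonlocal times, duration
        if times or duration is not None:
            dur = duration if duration is not None else (
                float(np.ceil(times[-1])) if times else 1.0)
            trains.append(SpikeTrain(times=np.asarray(times), duration=dur))
        times, duration = [], None

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("duration"):
                duration = float(body.split("=", 1)[1])
            continue
        times.append(float(line))
    flush()
    return trains


def model_to_config(model: HawkesModel) -> str:
    """Serialize a model to key = value text; lossless round trip."""
    kern = model.kernel
    lines = [
        f"nonlinearity = {model.phi.tag}",
        f"I0 = {model.I0!r}",
        f"tau_ref = {kern.refractory.tau_ref!r}",
    ]
    if isinstance(kern, SingleExpKernel):
        lines += ["kernel = single_exp", f"J = {kern.J!r}",
                  f"tau = {kern.tau!r}"]
    elif isinstance(kern, DoubleExpKernel):
        lines += ["kernel = double_exp", f"J_r = {kern.J_r!r}",
                  f"tau_r = {kern.tau_r!r}", f"J_a = {kern.J_a!r}",
                  f"tau_a = {kern.tau_a!r}"]
    elif isinstance(kern, BasisKernel):
        b = kern.basis
        lines += ["kernel = basis", f"n_basis = {b.n}",
                  f"peak_first = {b.peak_first!r}",
                  f"peak_last = {b.peak_last!r}", f"psi = {b.psi!r}",
                  "beta = " + ", ".join(repr(x) for x in kern.beta)]
    else:  # pragma: no cover
        raise TypeError(f"unknown kernel type {type(kern).__name__}")
    return "\n".join(lines) + "\n"


def _parse_kv(text: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def model_from_config(text: str) -> HawkesModel:
    kv = _parse_kv(text)
    phi = Nonlinearity(kv.get("nonlinearity", "exponential"))
    if "I0" in kv:
        I0 = float(kv["I0"])
    elif "c" in kv:
        I0 = float(np.log(float(kv["c"])))
    else:
        raise ValueError("config must set I0 or c")
    refr = RefractorySpec(tau_ref=float(kv.get("tau_ref", 0.002)))
    variant = kv.get("kernel", "single_exp")
    if variant == "single_exp":
        kernel = SingleExpKernel(J=float(kv["J"]), tau=float(kv["tau"]),
                                 refractory=refr)
    elif variant == "double_exp":
        kernel = DoubleExpKernel(J_r=float(kv["J_r"]),
                                 tau_r=float(kv["tau_r"]),
                                 J_a=float(kv["J_a"]),
                                 tau_a=float(kv["tau_a"]), refractory=refr)
    elif variant == "basis":
        basis = RaisedCosineBasis(n=int(kv.get("n_basis", 10)),
                                  peak_first=float(kv.get("peak_first",
                                                          0.002)),
                                  peak_last=float(kv.get("peak_last", 0.4)),
                                  psi=float(kv.get("psi", 0.002)))
        beta = tuple(float(x) for x in kv["beta"].split(","))
        kernel = BasisKernel(beta=beta, basis=basis, refractory=refr)
    else:
        raise ValueError(f"unknown kernel variant {variant!r}")
    return HawkesModel(I0=I0, kernel=kernel, phi=phi)


def write_config(path: PathLike, model: HawkesModel) -> None:
    Path(path).write_text(model_to_config(model))


def read_config(path: PathLike) -> HawkesModel:
    return model_from_config(Path(path).read_text())


def report_to_dict(report: StabilityReport) -> dict:
    """JSON-serializable view of a stability report."""
    return {
        "label": report.label,
        "lambda_thr": report.lambda_thr,
        "predicted_rate": report.predicted_rate,
        "t_div_bound": (None if report.t_div_bound is None
                        else (report.t_div_bound
                              if np.isfinite(report.t_div_bound) else "inf")),
        "fixed_points": [
            {"a0_hat": fp.a0_hat, "stable": fp.stable,
             "degenerate": fp.degenerate}
            for fp in report.fixed_points],
    }
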