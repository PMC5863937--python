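"""Plain-text file formats: schemes as JSON, trace sets and trajectories
as tab-separated tables with '#'-prefixed header metadata.

There is no community exchange format for kinetic gating schemes, so the
schema is versioned in-file (``hcngating-scheme-v1`` etc.) and kept
JSON-compatible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fitting import Trace, TraceSet
from .schemes import KineticScheme, ParameterSet
from .simulate import Trajectory, VoltageProtocol, open_probability


# -- schemes and parameters -------------------------------------------------

def save_scheme(scheme: KineticScheme, path, params: ParameterSet | None = None) -> None:
    doc = scheme.to_dict()
    if params is not None:
        doc["parameters"] = dict(params.values)
        doc["V_T"] = params.V_T
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_scheme(path) -> tuple[KineticScheme, ParameterSet | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "hcngating-scheme-v1":
        raise ValueError(f"{path}: not a hcngating scheme file")
    scheme = KineticScheme.from_dict(doc)
    params = None
    if "parameters" in doc:
        params = ParameterSet(dict(doc["parameters"]), V_T=doc.get("V_T", 25.4))
    return scheme, params


# -- trace sets -------------------------------------------------------------

def save_traceset(ts: TraceSet, path) -> None:
    """One file per traceset; per-trace blocks of time/P_o/sigma columns."""
    lines = ["# hcngating-traceset-v1", f"# condition\t{ts.condition}"]
    for key, val in sorted(ts.meta.items()):
        lines.append(f"# meta\t{key}\t{json.dumps(val)}")
    for tr in ts.traces:
        p = tr.protocol
        seg = ";".join(f"{v:g}:{d:g}" for v, d in p.segments)
        lines.append(
            f"# trace\t{p.name}\tholding={p.holding:g}\tsegments={seg}\tdt={p.sample_dt:g}"
        )
        for t, po, sg in zip(tr.times, tr.po, tr.sigma):
            lines.append(f"{t:.9g}\t{po:.9g}\t{sg:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_traceset(path) -> TraceSet:
    condition = ""
    meta: dict = {}
    traces: list[Trace] = []
    current: list[list[float]] | None = None
    proto: VoltageProtocol | None = None

    def flush():
        nonlocal current, proto
        if current is not None:
            arr = np.array(current)
            traces.append(
                Trace(protocol=proto, times=arr[:, 0], po=arr[:, 1], sigma=arr[:, 2])
            )
        current, proto = None, None

    for ln_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "condition" and len(parts) > 1:
                condition = parts[1]
            elif parts[0] == "meta":
                meta[parts[1]] = json.loads(parts[2])
            elif parts[0] == "trace":
                flush()
                fields = dict(p.split("=", 1) for p in parts[2:])
                segments = [
                    (float(v), float(d))
                    for v, d in (s.split(":") for s in fields["segments"].split(";"))
                ]
                proto = VoltageProtocol(
                    holding=float(fields["holding"]),
                    segments=segments,
                    sample_dt=float(fields["dt"]),
                    name=parts[1],
                )
                current = []
            continue
        try:
            vals = [float(v) for v in line.split("\t")]
        except ValueError as err:
            raise ValueError(f"{path}:{ln_no}: malformed data line {line!r}") from err
        if current is None:
            raise ValueError(f"{path}:{ln_no}: data before any '# trace' header")
        current.append(vals)
    flush()
    return TraceSet(traces=traces, condition=condition, meta=meta)


# -- trajectories -----------------------------------------------------------

def save_trajectory(traj: Trajectory, path) -> None:
    """TSV: time, one column per state, P_o; protocol metadata up top."""
    lines = ["# hcngating-trajectory-v1", f"# scheme\t{traj.scheme.name}"]
    if traj.protocol is not None:
        seg = ";".join(f"{v:g}:{d:g}" for v, d in traj.protocol.segments)
        lines.append(f"# protocol\tholding={traj.protocol.holding:g}\tsegments={seg}")
    lines.append("time\t" + "\t".join(traj.state_names) + "\tPo")
    po = open_probability(traj)
    for i, t in enumerate(traj.times):
        occ = "\t".join(f"{v:.9g}" for v in traj.occupancy[i])
        lines.append(f"{t:.9g}\t{occ}\t{po[i]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")
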