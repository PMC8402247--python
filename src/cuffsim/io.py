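"""Plain-text I/O: waveform files, scenario configs and tabular outputs.

The waveform format is a CSV dialect with a ``#``-prefixed header block:

    # cuffsim-waveform v1
    # meta {"seed": 7, ...}
    # channel cuff rate=125.0
    # channel ecg rate=500.0
    # t0 0.0
    time,cuff,ecg
    0.000000,0,0.01
    0.002000,,0.02
    ...

Rows run on the fastest channel's clock; slower channels fill only the rows
that fall on their own clock (blank otherwise).  Values round-trip at full
double precision.  Scenario configs are YAML mappings mirroring the
:class:`~cuffsim.synth.Scenario` fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .collapse import CollapseParams
from .features import Recording
from .simulate import CircuitParams, CuffProfile, SystemicWave
from .synth import Scenario
from .timing import TimingModel

__all__ = ["write_waveform", "read_waveform", "load_scenario", "dump_scenario"]

_MAGIC = "# cuffsim-waveform v1"


def write_waveform(rec: Recording, path) -> Path:
    """Write a recording to the columnar waveform format (lossless)."""
    path = Path(path)
    names = list(rec.channels)
    fs_max = max(rec.rates.values())
    n_rows = max(int(round(len(rec.channels[c]) * fs_max / rec.rates[c]))
                 for c in names)
    strides = {c: fs_max / rec.rates[c] for c in names}
    for c, s in strides.items():
        if abs(s - round(s)) > 1e-9:
            raise ValueError(f"write_waveform: rate of {c!r} does not divide the master rate")
    with path.open("w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("# meta " + json.dumps(rec.meta, sort_keys=True) + "\n")
        for c in names:
            fh.write(f"# channel {c} rate={rec.rates[c]:.6g}\n")
        fh.write(f"# t0 {rec.t0!r}\n")
        fh.write("time," + ",".join(names) + "\n")
        cols = {c: rec.channels[c] for c in names}
        for i in range(n_rows):
            t = rec.t0 + i / fs_max
            cells = [f"{t:.6f}"]
            for c in names:
                step = int(round(strides[c]))
                if i % step == 0 and i // step < len(cols[c]):
                    cells.append(repr(float(cols[c][i // step])))
                else:
                    cells.append("")
            fh.write(",".join(cells) + "\n")
    return path


def read_waveform(path) -> Recording:
    """Read a waveform file written by :func:`write_waveform`."""
    path = Path(path)
    meta: dict = {}
    rates: dict = {}
    t0 = 0.0
    header_done = False
    names: list = []
    data: dict = {}
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise ValueError(f"{path}: line 1: not a cuffsim waveform file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not header_done:
                if line.startswith("# meta "):
                    meta = json.loads(line[len("# meta "):])
                elif line.startswith("# channel "):
                    try:
                        _, _, name, rate_kv = line.split(" ", 3)
                        rates[name] = float(rate_kv.split("=", 1)[1])
                    except (ValueError, IndexError) as exc:
                        raise ValueError(f"{path}: line {lineno}: malformed channel header") from exc
                elif line.startswith("# t0 "):
                    t0 = float(line[len("# t0 "):])
                elif line.startswith("time,"):
                    names = line.split(",")[1:]
                    missing = set(rates) - set(names)
                    if missing or not names:
                        raise ValueError(f"{path}: line {lineno}: column/channel "
                                         f"mismatch (missing {sorted(missing)})")
                    data = {c: [] for c in names}
                    header_done = True
                elif not line.startswith("#"):
                    raise ValueError(f"{path}: line {lineno}: unexpected content before column row")
            else:
                cells = line.split(",")
                for c, cell in zip(names, cells[1:]):
                    if cell != "":
                        data[c].append(float(cell))
    if not header_done:
        raise ValueError(f"{path}: no data header found")
    channels = {c: np.asarray(v) for c, v in data.items()}
    fs_max = max(rates.values())
    for c in names:
        expect = len(channels[names[0]]) * rates[c] / rates[names[0]]
        if abs(len(channels[c]) - expect) > 1:
            raise ValueError(f"{path}: channel {c!r} length {len(channels[c])} "
                             f"inconsistent with rate {rates[c]} Hz")
    return Recording(channels=channels, rates=rates, t0=t0, meta=meta)


def load_scenario(path) -> Scenario:
    """Build a :class:`Scenario` from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kw = {}
    if "wave" in cfg:
        kw["wave"] = SystemicWave(**cfg["wave"])
    if "cuff" in cfg:
        kw["cuff"] = CuffProfile(**cfg["cuff"])
    if "circuit" in cfg:
        kw["circuit"] = CircuitParams(**cfg["circuit"])
    if "collapse" in cfg:
        kw["collapse"] = CollapseParams(**cfg["collapse"])
    if "timing" in cfg and cfg["timing"] is not None:
        kw["timing"] = TimingModel(**cfg["timing"])
    for key in ("noise_sd", "drift_amp", "drift_freq", "seed", "pep", "transit_base"):
        if key in cfg:
            kw[key] = cfg[key]
    if "artifacts" in cfg:
        kw["artifacts"] = tuple(tuple(a) for a in cfg["artifacts"])
    return Scenario(**kw)


def dump_scenario(s: Scenario, path) -> Path:
    """Serialise a scenario to YAML (inverse of :func:`load_scenario`)."""
    from dataclasses import asdict

    cfg = {
        "wave": asdict(s.wave),
        "cuff": asdict(s.cuff),
        "circuit": asdict(s.circuit),
        "collapse": asdict(s.collapse),
        "timing": None if s.timing is None else asdict(s.timing),
        "noise_sd": s.noise_sd,
        "drift_amp": s.drift_amp,
        "drift_freq": s.drift_freq,
        "artifacts": [list(a) for a in s.artifacts],
        "seed": s.seed,
        "pep": s.pep,
        "transit_base": s.transit_base,
    }
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
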