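"""Plain-text file formats for windows, PMFs, paths, reports and configs.

All formats are whitespace-separated, '.'-decimal, locale-free, and
round-trip exactly: write → read → write is byte-identical.  Numeric values
are printed with ``repr``-exact ``%.17g`` formatting so reread values equal
the originals bit-for-bit.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import json
import re
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import __version__
from .mep import MinimumEnergyPath
from .umbrella import BiasPotential, UmbrellaWindow
from .wham import PMFGrid

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "write_window",
    "read_window",
    "write_pmf",
    "read_pmf",
    "write_path",
    "read_path",
    "write_report",
    "read_report",
    "format_pm",
    "parse_pm",
]

_G = "%.17g"  # exact round-trip float formatting


def _fmt(x) -> str:
    return _G % float(x)


@dataclass
class PipelineConfig:
    """Resolved parameters of a pipeline run.

    Defaults are the standard permeation protocol: 300 K, k = 10 kcal/mol/Å²,
    1.0 Å window spacing, 0.5 ns windows with 50 ps equilibration, 200-node
    strings converged to 1e-3 Å, 3 blocks of 150 ps, coordination cutoffs
    2.8/3.2 Å, snapshots every 20 ps.
    """

    temperature: float = 300.0  # K
    force_constant: float = 10.0  # kcal/mol/Å²
    window_spacing: float = 1.0  # Å
    window_duration: float = 500.0  # ps
    equilibration: float = 50.0  # ps
    sample_stride: float = 1.0  # ps
    bin_width_1d: float = 0.1  # Å
    bin_width_2d: float = 0.25  # Å
    string_nodes: int = 200
    string_tol: float = 1e-3  # Å
    n_blocks: int = 3
    block_duration: float = 150.0  # ps
    cutoff_na: float = 2.8  # Å
    cutoff_k: float = 3.2  # Å
    snapshot_stride: float = 20.0  # ps
    diffusion: float = 0.1  # Å²/ps
    dt: float = 0.01  # ps
    seed: int = 2012

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        """Read a key = value config file with [section] headers."""
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs = {}
        valid = {f.name: f.type for f in fields(cls)}
        for section in cp.sections():
            for key, val in cp.items(section):
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                typ = int if valid[key] in (int, "int") else float
                kwargs[key] = typ(float(val)) if typ is int else typ(val)
        return cls(**kwargs)

    def dump(self, path):
        cp = configparser.ConfigParser()
        cp["protocol"] = {
            k: str(getattr(self, k))
            for k in (
                "temperature", "force_constant", "window_spacing",
                "window_duration", "equilibration", "sample_stride",
            )
        }
        cp["analysis"] = {
            k: str(getattr(self, k))
            for k in (
                "bin_width_1d", "bin_width_2d", "string_nodes", "string_tol",
                "n_blocks", "block_duration", "cutoff_na", "cutoff_k",
                "snapshot_stride",
            )
        }
        cp["sampler"] = {k: str(getattr(self, k)) for k in ("diffusion", "dt", "seed")}
        with open(path, "w") as fh:
            cp.write(fh)

    def resolved_items(self) -> list:
        return sorted(asdict(self).items())


@dataclass
class RunManifest:
    """Provenance record: inputs, resolved config, version, timings, seed."""

    inputs: list = field(default_factory=list)  # (path, sha256)
    config: dict = field(default_factory=dict)
    version: str = ""
    timings: dict = field(default_factory=dict)
    seed: int = 0

    @staticmethod
    def checksum(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        return h.hexdigest()

    def add_input(self, path):
        self.inputs.append((str(path), self.checksum(path)))

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "inputs": self.inputs,
                    "config": self.config,
                    "version": self.version or __version__,
                    "timings": self.timings,
                    "seed": self.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


# -- window files -----------------------------------------------------------


def write_window(window: UmbrellaWindow, path):
    buf = io.StringIO()
    c = ",".join(_fmt(v) for v in window.bias.center)
    buf.write(f"# center={c}\n")
    buf.write(f"# k={_fmt(window.bias.k)}\n")
    buf.write(f"# stride_ps={_fmt(window.stride)}\n")
    buf.write(f"# t0_ps={_fmt(window.t0)}\n")
    buf.write(f"# equil_discarded_ps={_fmt(window.equil_discarded)}\n")
    if window.label:
        buf.write(f"# label={window.label}\n")
    times = window.times
    for t, row in zip(times, window.samples):
        buf.write(" ".join([_fmt(t)] + [_fmt(v) for v in row]) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_window(path) -> UmbrellaWindow:
    header = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
                continue
            parts = line.split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed data line {line!r}") from None
    for req in ("center", "k", "stride_ps"):
        if req not in header:
            raise ValueError(f"{path}: missing required header '# {req}='")
    center = tuple(float(v) for v in header["center"].split(","))
    bias = BiasPotential(center, float(header["k"]))
    if not rows:
        raise ValueError(f"{path}: no samples")
    data = np.array(rows)
    if data.shape[1] != 1 + bias.dim:
        raise ValueError(
            f"{path}: rows have {data.shape[1]} columns, expected {1 + bias.dim}"
        )
    return UmbrellaWindow(
        bias=bias,
        samples=data[:, 1:],
        stride=float(header["stride_ps"]),
        t0=float(header.get("t0_ps", data[0, 0])),
        equil_discarded=float(header.get("equil_discarded_ps", 0.0)),
        label=header.get("label", ""),
    )


# -- PMF files --------------------------------------------------------------


def write_pmf(pmf: PMFGrid, path):
    buf = io.StringIO()
    buf.write(f"# dim={pmf.dim}\n")
    for d, c in enumerate(pmf.centers):
        w = c[1] - c[0] if len(c) > 1 else 0.0
        buf.write(f"# axis{d} x0={_fmt(c[0])} dx={_fmt(w)} n={len(c)}\n")
    buf.write(f"# temperature_K={_fmt(pmf.temperature)}\n")
    buf.write(f"# zero={pmf.zero_convention}\n")
    if pmf.dim == 1:
        for x, v, c in zip(pmf.centers[0], pmf.values, pmf.counts):
            buf.write(f"{_fmt(x)} {_fmt(v)} {_fmt(c)}\n")
    else:
        buf.write("# values (rows: axis0, cols: axis1; nan = unsampled)\n")
        for row in pmf.values:
            buf.write(" ".join(_fmt(v) for v in row) + "\n")
        buf.write("# counts\n")
        for row in pmf.counts:
            buf.write(" ".join(_fmt(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_pmf(path) -> PMFGrid:
    axes = {}
    temperature = 300.0
    zero = "min-zero"
    dim = None
    data_rows, count_rows = [], []
    section = "values"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("dim="):
                    dim = int(body.split("=")[1])
                elif body.startswith("axis"):
                    m = re.match(r"axis(\d+) x0=(\S+) dx=(\S+) n=(\d+)", body)
                    if m:
                        d = int(m.group(1))
                        x0, dx, n = float(m.group(2)), float(m.group(3)), int(m.group(4))
                        axes[d] = x0 + dx * np.arange(n)
                elif body.startswith("temperature_K="):
                    temperature = float(body.split("=")[1])
                elif body.startswith("zero="):
                    zero = body.split("=", 1)[1]
                elif body == "counts":
                    section = "counts"
                continue
            row = [float(v) for v in line.split()]
            (count_rows if section == "counts" else data_rows).append(row)
    if dim is None:
        raise ValueError(f"{path}: missing '# dim=' header")
    centers = tuple(axes[d] for d in range(dim))
    if dim == 1:
        arr = np.array(data_rows)
        values, counts = arr[:, 1], arr[:, 2]
    else:
        values = np.array(data_rows)
        counts = np.array(count_rows)
    mask = np.isfinite(values)
    return PMFGrid(
        centers=centers,
        values=values,
        mask=mask,
        counts=counts,
        temperature=temperature,
        zero_convention=zero,
    )


# -- path files -------------------------------------------------------------


def write_path(path_obj: MinimumEnergyPath, path):
    buf = io.StringIO()
    buf.write(f"# iterations={path_obj.iterations}\n")
    buf.write(f"# final_rms_A={_fmt(path_obj.final_rms)}\n")
    buf.write(f"# converged={int(path_obj.converged)}\n")
    buf.write("# columns: index d1 d2 arc_length free_energy\n")
    for i, (node, s, f) in enumerate(
        zip(path_obj.nodes, path_obj.arc_length, path_obj.free_energy)
    ):
        buf.write(f"{i} {_fmt(node[0])} {_fmt(node[1])} {_fmt(s)} {_fmt(f)}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_path(path) -> MinimumEnergyPath:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                key, _, val = body.partition("=")
                if val:
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(v) for v in line.split()])
    data = np.array(rows)
    return MinimumEnergyPath(
        nodes=data[:, 1:3],
        arc_length=data[:, 3],
        free_energy=data[:, 4],
        iterations=int(meta.get("iterations", 0)),
        final_rms=float(meta.get("final_rms_A", np.nan)),
        converged=bool(int(meta.get("converged", 0))),
    )


# -- block reports ----------------------------------------------------------

_PM_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*±\s*([-+0-9.eE]+)(\s*kcal/mol)?\s*$")


def format_pm(value: float, std: float, digits: int = 1) -> str:
    """Render ``value ± std`` the way free-energy papers print it."""
    return f"{value:.{digits}f}±{std:.{digits}f} kcal/mol"


def parse_pm(text: str) -> tuple:
    m = _PM_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse ± value from {text!r}")
    return float(m.group(1)), float(m.group(2))


def write_report(estimates, path):
    """Tabulate block estimates: quantity, full value, blocks, mean, std."""
    buf = io.StringIO()
    n_blocks = max(len(e.block_values) for e in estimates)
    cols = ["quantity", "full"] + [f"block{i+1}" for i in range(n_blocks)] + ["mean", "std"]
    buf.write("# " + "\t".join(cols) + "\n")
    for e in estimates:
        row = [e.label, _fmt(e.full_value if e.full_value is not None else e.mean)]
        row += [_fmt(v) for v in e.block_values]
        row += [_fmt(e.mean), _fmt(e.std)]
        buf.write("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_report(path) -> list:
    from .blocks import BlockEstimate, BlockScheme

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[0]
            full = float(parts[1])
            blocks = [float(v) for v in parts[2:-2]]
            mean, std = float(parts[-2]), float(parts[-1])
            out.append(
                BlockEstimate(
                    label=label,
                    block_values=blocks,
                    mean=mean,
                    std=std,
                    full_value=full,
                    scheme=BlockScheme(n_blocks=len(blocks)),
                )
            )
    return out
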