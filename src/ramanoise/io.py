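"""File formats, run configuration, and seed bookkeeping.

Formats
    Spectrum     two-column text (wavenumber cm^-1, intensity counts),
                 whitespace- or comma-delimited, '#' comment lines preserved
                 as header metadata.
    Noise bank   CSV (first row = wavenumber axis, then one spectrum per
                 row) or HDF5 (/bank m x n channels-by-spectra, /wavenumber,
                 /integration_times_s, attributes).
    HyperCube    HDF5: /intensity (rows, cols, bands) float32, /wavenumber
                 (bands) float64, attributes pixel_size and dwell_time.

Seeds
    A single run seed fans out to per-component sub-seeds keyed by component
    name (SHA-256 based), so adding a component never shifts the random
    streams of the others.  Every artifact writer records the seed and a
    config hash so a run is replayable from its logs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .aunet import ModelConfig
from .denoise import HyperCube
from .errors import ConfigError, ParseError
from .noise import NoiseBank, NoiseSimConfig
from .synth import GeneratorConfig, SpectralAxis, Spectrum
from .training import TrainConfig

__all__ = [
    "read_spectrum", "write_spectrum", "read_cube", "write_cube",
    "read_noise_bank", "write_noise_bank", "derive_seed", "config_hash",
    "RunConfig", "load_run_config", "dump_run_config",
]


# -- spectra ---------------------------------------------------------------

def read_spectrum(path) -> Spectrum:
    """Parse a two-column text spectrum; reports the line number on bad rows."""
    path = Path(path)
    wn, counts, header = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header.append(stripped.lstrip("#").strip())
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"expected two columns, got {stripped!r}", lineno)
            try:
                wn.append(float(parts[0]))
                counts.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"non-numeric row {stripped!r}", lineno) from None
    if len(wn) < 2:
        raise ParseError(f"{path} contains fewer than 2 data rows")
    w = np.asarray(wn)
    d = np.diff(w)
    if not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmax(np.sign(d) != np.sign(d[0]))) + 2
        raise ParseError("wavenumber axis is not monotone", bad)
    if d[0] < 0:
        w, counts = w[::-1].copy(), counts[::-1]
    return Spectrum(w, np.asarray(counts, dtype=float), tuple(header))


def write_spectrum(spectrum: Spectrum, path, extra_header: tuple[str, ...] = ()) -> None:
    """Write a spectrum losslessly at float64 text precision."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in (*spectrum.header, *extra_header):
            fh.write(f"# {line}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.17g} {y:.17g}\n")


# -- hyperspectral cubes ---------------------------------------------------

def write_cube(cube: HyperCube, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("intensity", data=cube.data.astype(np.float32))
        fh.create_dataset("wavenumber", data=cube.axis.grid.astype(np.float64))
        if cube.pixel_size is not None:
            fh.attrs["pixel_size"] = cube.pixel_size
        if cube.dwell_time is not None:
            fh.attrs["dwell_time"] = cube.dwell_time
        for key, value in cube.metadata.items():
            fh.attrs[f"meta_{key}"] = value


def read_cube(path) -> HyperCube:
    with h5py.File(path, "r") as fh:
        for name in ("intensity", "wavenumber"):
            if name not in fh:
                raise ParseError(f"cube file is missing dataset /{name}")
        data = fh["intensity"][...].astype(float)
        axis = SpectralAxis.from_grid(fh["wavenumber"][...])
        pixel_size = fh.attrs.get("pixel_size")
        dwell_time = fh.attrs.get("dwell_time")
        meta = {k[5:]: _attr_py(v) for k, v in fh.attrs.items() if k.startswith("meta_")}
    return HyperCube(data, axis,
                     None if pixel_size is None else float(pixel_size),
                     None if dwell_time is None else float(dwell_time), meta)


def _attr_py(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


# -- noise banks -----------------------------------------------------------

def write_noise_bank(bank: NoiseBank, path) -> None:
    """Write a bank as CSV (.csv: one spectrum per row) or HDF5 (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        header = ",".join(f"{w:.17g}" for w in bank.axis.grid)
        # rows are spectra on disk; in memory spectra are columns
        np.savetxt(path, bank.matrix.T, delimiter=",", header=header, comments="# ")
        return
    with h5py.File(path, "w") as fh:
        fh.create_dataset("bank", data=bank.matrix)
        fh.create_dataset("wavenumber", data=bank.axis.grid)
        if bank.integration_times_s is not None:
            fh.create_dataset("integration_times_s", data=bank.integration_times_s)
        fh.attrs["metadata"] = json.dumps(bank.metadata, default=str)


def read_noise_bank(path) -> NoiseBank:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path) as fh:
            first = fh.readline().strip()
        if not first.startswith("#"):
            raise ParseError("CSV bank must start with a '# <wavenumber axis>' row", 1)
        axis_vals = np.array([float(v) for v in first.lstrip("#").split(",")])
        rows = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        return NoiseBank(rows.T, SpectralAxis.from_grid(axis_vals))
    with h5py.File(path, "r") as fh:
        for name in ("bank", "wavenumber"):
            if name not in fh:
                raise ParseError(f"bank file is missing dataset /{name}")
        matrix = fh["bank"][...]
        axis = SpectralAxis.from_grid(fh["wavenumber"][...])
        times = fh["integration_times_s"][...] if "integration_times_s" in fh else None
        meta = json.loads(fh.attrs.get("metadata", "{}"))
    return NoiseBank(matrix, axis, times, meta)


# -- seeds and hashes ------------------------------------------------------

def derive_seed(master_seed: int, component: str) -> int:
    """Stable component-keyed sub-seed in [0, 2^31)."""
    digest = hashlib.sha256(f"{int(master_seed)}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(cfg) -> str:
    """Short SHA-256 of a config dataclass (or dict) in canonical JSON."""
    payload = asdict(cfg) if is_dataclass(cfg) else dict(cfg)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# -- run configuration -----------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything needed to replay a training run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    noise_sim: NoiseSimConfig = field(default_factory=NoiseSimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise_bank_path: str | None = None
    output_path: str | None = None
    seed: int = 0

    def component_seed(self, component: str) -> int:
        return derive_seed(self.seed, component)


_TUPLE_FIELDS = {"n_peaks_range", "fwhm_range", "position_range", "amplitude_range",
                 "baseline_n_range", "baseline_fwhm_range", "target_snr_db",
                 "integration_times_s"}


def _build_dataclass(cls, data: dict):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data)}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown {cls.__name__} field {key!r}")
        if key == "axis" and isinstance(value, dict):
            value = SpectralAxis(**value)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("run config must be a YAML mapping")
    unknown = set(data) - {f.name for f in fields(RunConfig)}
    if unknown:
        raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
    return RunConfig(
        generator=_build_dataclass(GeneratorConfig, data.get("generator")),
        noise_sim=_build_dataclass(NoiseSimConfig, data.get("noise_sim")),
        model=_build_dataclass(ModelConfig, data.get("model")),
        train=_build_dataclass(TrainConfig, data.get("train")),
        noise_bank_path=data.get("noise_bank_path"),
        output_path=data.get("output_path"),
        seed=int(data.get("seed", 0)),
    )


def dump_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
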