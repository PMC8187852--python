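"""Readers/writers for COLVAR/HILLS-dialect tables and run configuration.

The table dialect is the whitespace-delimited format of the enhanced-
sampling ecosystem: a header line ``#! FIELDS name1 name2 ...`` followed by
one numeric row per record; additional ``#``-prefixed lines are comments.
Numbers are written in scientific notation with enough digits that a
write→read round trip is lossless to 12 significant figures.

Configuration is structured YAML with blocks ``system``, ``integrator``,
``metad``, ``metainference`` and ``analysis``; an explicit ``seed`` is
mandatory (every run is seed-pinned) and unknown keys are rejected.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cvs import CoordinateCV
from .dynamics import IntegratorConfig
from .metad import BiasState, Hill, MetaDConfig, default_grid_range
from . import systems

__all__ = [
    "ColvarTable",
    "RunConfig",
    "ConfigError",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "rebuild_bias",
    "load_config",
]

_FMT = " %.12e"   # lossless to 12 significant digits


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class ColvarTable:
    """A named numeric table read from/written to the COLVAR dialect."""

    fields: list
    data: np.ndarray
    source: str | None = None

    def __post_init__(self):
        self.fields = list(self.fields)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size and self.data.shape[1] != len(self.fields):
            raise ValueError("column count does not match field count")

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.fields.index(name)]

    def __len__(self) -> int:
        return 0 if self.data.size == 0 else self.data.shape[0]


def read_colvar(path, require_time: bool = True) -> ColvarTable:
    """Parse a COLVAR-dialect table; errors carry the offending line number."""
    path = Path(path)
    fields = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                parts = stripped.split()
                if len(parts) >= 2 and parts[1] == "FIELDS":
                    if fields is None:
                        fields = parts[2:]
                    continue
                continue
            if stripped.startswith("#"):
                continue
            if fields is None:
                raise ValueError(
                    f"{path}:{lineno}: data before the '#! FIELDS' header")
            vals = stripped.split()
            if len(vals) != len(fields):
                raise ValueError(
                    f"{path}:{lineno}: row has {len(vals)} columns, "
                    f"header declares {len(fields)}")
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if fields is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(fields)))
    table = ColvarTable(fields=fields, data=data, source=str(path))
    if require_time:
        if "time" not in fields:
            raise ValueError(f"{path}: no 'time' column")
        t = table.column("time")
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ValueError(f"{path}: time column must be non-decreasing")
    return table


def write_colvar(table: ColvarTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(table.fields) + "\n")
        for row in np.atleast_2d(table.data):
            fh.write("".join(_FMT % v for v in row).lstrip() + "\n")


_HILLS_REQUIRED = ("time", "height")


def write_hills(hills: list, cv_names, path, biasfactor: float = 10.0) -> None:
    """HILLS-dialect output: time, per-CV centers and sigmas, height, biasf.

    In pb mode every hill lives on one CV; centers/sigmas of the other CVs
    are written as NaN placeholders so all rows share one schema.
    """
    cv_names = list(cv_names)
    fields = (["time"] + [f"center_{c}" for c in cv_names]
              + [f"sigma_{c}" for c in cv_names] + ["height", "biasf"])
    rows = []
    for h in hills:
        centers = np.full(len(cv_names), np.nan)
        sigmas = np.full(len(cv_names), np.nan)
        if h.cv_name is None:
            centers[:] = h.center
            sigmas[:] = h.sigma
        else:
            i = cv_names.index(h.cv_name)
            centers[i] = h.center[0]
            sigmas[i] = h.sigma[0]
        rows.append([h.time, *centers, *sigmas, h.height, biasfactor])
    table = ColvarTable(fields=fields,
                        data=np.array(rows) if rows else np.empty((0, len(fields))))
    write_colvar(table, path)


def read_hills(path) -> ColvarTable:
    table = read_colvar(path, require_time=False)
    for col in _HILLS_REQUIRED:
        if col not in table.fields:
            raise ValueError(f"{path}: missing required column {col!r}")
    if not any(f.startswith("center_") for f in table.fields):
        raise ValueError(f"{path}: no center_<cv> columns")
    if not any(f.startswith("sigma_") for f in table.fields):
        raise ValueError(f"{path}: no sigma_<cv> columns")
    return table


def hills_from_table(table: ColvarTable, cv_names) -> list:
    """Rebuild Hill objects from a HILLS-dialect table."""
    cv_names = list(cv_names)
    hills = []
    centers = np.stack([table.column(f"center_{c}") for c in cv_names], axis=1)
    sigmas = np.stack([table.column(f"sigma_{c}") for c in cv_names], axis=1)
    times = table.column("time")
    heights = table.column("height")
    for t, c, s, h in zip(times, centers, sigmas, heights):
        present = ~np.isnan(c)
        if present.all():
            hills.append(Hill(time=t, center=c, sigma=s, height=h))
        else:
            i = int(np.nonzero(present)[0][0])
            hills.append(Hill(time=t, center=c[i:i + 1], sigma=s[i:i + 1],
                              height=h, cv_name=cv_names[i]))
    return hills


def rebuild_bias(table: ColvarTable, cfg: MetaDConfig, kT: float) -> BiasState:
    """Reconstruct a BiasState (grids included) from a written HILLS table."""
    bias = BiasState(cfg, kT=kT)
    for h in hills_from_table(table, cfg.cv_names):
        bias.hills.append(h)
        if cfg.mode == "joint":
            if bias.n_cvs == 1:
                bias.joint_grid.add_gaussian(h.center[0], h.sigma[0], h.height)
            else:
                bias.joint_grid.add_gaussian(h.center, h.sigma, h.height)
        else:
            i = cfg.cv_names.index(h.cv_name)
            bias.grids[i].add_gaussian(h.center[0], h.sigma[0], h.height)
    return bias


# ---------------------------------------------------------------------------
# configuration

KT_PER_KJMOL_340K = 1.0 / (0.008314462618 * 340.0)   # physical-unit parity mode

_TOP_KEYS = {"seed", "units", "system", "cvs", "integrator", "metad",
             "metainference", "analysis"}
_SYSTEM_KEYS = {"name", "populations", "barrier", "width", "centers"}
_INTEGRATOR_KEYS = {"dt", "n_steps", "kT", "friction", "save_stride"}
_METAD_KEYS = {"mode", "cvs", "height", "pace", "biasfactor", "sigma",
               "grid", "walkers"}
_MI_KEYS = {"targets", "stride", "averaging", "replicas", "lambda"}
_ANALYSIS_KEYS = {"cv", "bins", "range", "partition", "n_blocks", "discard",
                  "block_lengths"}

# printed defaults of the reference setup: bias factor 10, initial hill
# height 0.5 kJ/mol, 10 walkers, restraints every 2 steps, averaging = pace
DEFAULT_BIASFACTOR = 10.0
DEFAULT_HEIGHT_KJMOL = 0.5
DEFAULT_WALKERS = 10
DEFAULT_RESTRAINT_STRIDE = 2
DEFAULT_PACE = 250


@dataclass
class RunConfig:
    """Validated run configuration assembled from a YAML file."""

    seed: int
    units: str
    kT: float
    system: systems.ToySystem
    integrator: IntegratorConfig
    metad: MetaDConfig
    n_walkers: int
    metainference: dict | None
    analysis: dict
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _check_keys(block: dict, allowed: set, where: str):
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {', '.join(unknown)}")


def _build_system(block: dict) -> systems.ToySystem:
    _check_keys(block, _SYSTEM_KEYS, "system")
    name = block.get("name", "three_well_2d")
    if name == "three_well_2d":
        return systems.three_well_2d(tuple(block.get("populations", (0.55, 0.15, 0.30))))
    if name == "two_state_1d":
        return systems.two_state_1d(tuple(block.get("populations", (0.5, 0.5))),
                                    width=float(block.get("width", 0.3)))
    if name == "double_well_1d":
        return systems.double_well_1d(barrier_kT=float(block.get("barrier", 8.0)))
    raise ConfigError(f"unknown system name {name!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration with documented defaults."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "the top level")
    if "seed" not in raw:
        raise ConfigError("an explicit 'seed' is required (runs are seed-pinned)")
    seed = int(raw["seed"])

    units = raw.get("units", "kT")
    if units not in ("kT", "physical"):
        raise ConfigError(f"units must be 'kT' or 'physical', got {units!r}")
    kT = 1.0 if units == "kT" else 1.0 / KT_PER_KJMOL_340K

    system = _build_system(raw.get("system", {}) or {})

    integ = dict(raw.get("integrator", {}) or {})
    _check_keys(integ, _INTEGRATOR_KEYS, "integrator")
    integ_cfg = IntegratorConfig(
        dt=float(integ.get("dt", 0.004)),
        n_steps=int(integ.get("n_steps", 100_000)),
        kT=float(integ.get("kT", kT)),
        friction=float(integ.get("friction", 1.0)),
        seed=seed,
        save_stride=int(integ.get("save_stride", 10)),
    )

    metad = dict(raw.get("metad", {}) or {})
    _check_keys(metad, _METAD_KEYS, "metad")
    default_height = (DEFAULT_HEIGHT_KJMOL if units == "physical"
                      else DEFAULT_HEIGHT_KJMOL * KT_PER_KJMOL_340K)
    cv_names = metad.get("cvs")
    if cv_names is None:
        cv_names = [cv.name for cv in system.cvs
                    if isinstance(cv, CoordinateCV)] or [system.cvs[0].name]
    cvs = tuple(system.cv(str(n)) for n in cv_names)
    sigma_block = metad.get("sigma", {})
    if isinstance(sigma_block, dict):
        sigma = tuple(float(sigma_block.get(cv.name, 0.1)) for cv in cvs)
    else:
        sigma = tuple(float(s) for s in np.atleast_1d(sigma_block))
    grid_block = metad.get("grid", {}) or {}
    gmin, gmax, gbins = [], [], []
    for cv in cvs:
        if cv.name in grid_block:
            lo, hi, nb = grid_block[cv.name]
        else:
            lo, hi = default_grid_range(system.spec, cv)
            nb = None
        gmin.append(float(lo))
        gmax.append(float(hi))
        gbins.append(nb)
    bins = None if any(b is None for b in gbins) else tuple(int(b) for b in gbins)
    try:
        metad_cfg = MetaDConfig(
            cvs=cvs,
            sigma=sigma,
            grid_min=tuple(gmin),
            grid_max=tuple(gmax),
            grid_bins=bins,
            mode=str(metad.get("mode", "pb")),
            height=float(metad.get("height", default_height)),
            pace=int(metad.get("pace", DEFAULT_PACE)),
            biasfactor=float(metad.get("biasfactor", DEFAULT_BIASFACTOR)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    n_walkers = int(metad.get("walkers", DEFAULT_WALKERS))

    mi = raw.get("metainference")
    if mi is not None:
        mi = dict(mi)
        _check_keys(mi, _MI_KEYS, "metainference")
        mi.setdefault("stride", DEFAULT_RESTRAINT_STRIDE)
        mi.setdefault("averaging", metad_cfg.pace)
        mi.setdefault("replicas", n_walkers)
        mi.setdefault("lambda", 1.0)

    analysis = dict(raw.get("analysis", {}) or {})
    _check_keys(analysis, _ANALYSIS_KEYS, "analysis")

    return RunConfig(seed=seed, units=units, kT=integ_cfg.kT, system=system,
                     integrator=integ_cfg, metad=metad_cfg,
                     n_walkers=n_walkers, metainference=mi,
                     analysis=analysis, raw=raw)
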