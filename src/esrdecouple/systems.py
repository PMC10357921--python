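"""Bundled spin-system definitions and the YAML config loader.

Four reference systems ship with the package, spanning the two regimes the
pseudo-decoupling workflow targets:

* ``R1`` — 9,10-dimethylanthracene cation: isotropic, 175-line spectrum
  (six equivalent methyl protons, four ortho and four meta ring protons).
* ``R2`` — a bridged biaryl (6-hydrodipyridoimidazole-type) cation with a
  dense super-hyperfine spectrum.  Its published simulation-parameter table
  is internally inconsistent, so this definition is *reconstructed* from
  the extracted couplings (CH2 pair 24.2 G; two 14N 4.35 G; ring-proton
  pairs 2.6, 2.4 and 0.65 G) and is flagged as such.
* ``M1`` — copper phthalocyanine-type Cu(2+)-N4 adduct.  The reference
  regime is slow-motional, which first-order simulation cannot reach; the
  bundled definition is a frozen axial-powder stand-in for demonstration,
  not for quantitative comparison.
* ``M2`` — an axial frozen-powder Cu(2+)-N4 adduct (63Cu I=3/2 quartet,
  four equivalent 14N).

Each definition carries per-band (L 1.4 / S 3.3 / X 9.8 GHz) linewidths,
field grids and the working decomposition level ``j_star`` used in the
reference analysis, so every downstream stage is reproducible from the
config alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import InvalidInputError
from .simulate import (
    FieldGrid,
    NucleusGroup,
    SpinSystem,
    simulate_axial_powder,
    simulate_isotropic,
)
from .spectrum import Spectrum

__all__ = ["SystemConfig", "available_systems", "load_system", "simulate_system"]

_ALIASES = {"r1": "R1", "r-i": "R1", "r2": "R2", "r-ii": "R2",
            "m1": "M1", "m-i": "M1", "m2": "M2", "m-ii": "M2"}


@dataclass(frozen=True)
class SystemConfig:
    """A fully resolved simulation request: system + band + grid + level."""

    system: SpinSystem
    kind: str  # 'isotropic' | 'axial_powder'
    mw_freq_GHz: float
    grid: FieldGrid | None
    j_star: int | None
    shf_levels: tuple[int, ...] | None
    band: str | None
    name: str


def available_systems() -> list[str]:
    """Names of the bundled system definitions."""
    pkg = resources.files(__package__) / "systems"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def _read_config(source: str | Path) -> dict:
    key = str(source).lower()
    if key in _ALIASES:
        source = _ALIASES[key]
    candidate = Path(str(source))
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        text = candidate.read_text()
    else:
        res = resources.files(__package__) / "systems" / f"{source}.yaml"
        if not res.is_file():
            raise InvalidInputError(
                f"unknown system {source!r}; bundled: {available_systems()}, "
                "or pass a YAML path"
            )
        text = res.read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise InvalidInputError(f"config {source!r} is not a mapping")
    return cfg


def _parse_nuclei(raw: list) -> tuple[NucleusGroup, ...]:
    groups = []
    for item in raw or []:
        a = item["A"]
        groups.append(
            NucleusGroup(
                A=tuple(a) if isinstance(a, (list, tuple)) else float(a),
                I=float(item["I"]),
                n=int(item.get("n", 1)),
                label=str(item.get("label", "")),
            )
        )
    return tuple(groups)


def _parse_grid(raw: dict | None) -> FieldGrid | None:
    if raw is None:
        return None
    return FieldGrid(float(raw["start_G"]), float(raw["stop_G"]), int(raw["points"]))


def load_system(source: str | Path, band: str | None = None) -> SystemConfig:
    """Load a bundled system by name (``R1``/``R2``/``M1``/``M2``) or a YAML path.

    Banded configs (with a ``bands:`` mapping) need ``band`` (``L``/``S``/``X``);
    flat configs carry ``mw_freq_GHz`` and ``linewidth`` at top level.
    """
    cfg = _read_config(source)
    name = str(cfg.get("name", source))
    kind = str(cfg.get("kind", "isotropic"))
    if kind not in ("isotropic", "axial_powder"):
        raise InvalidInputError(f"{name}: kind must be isotropic|axial_powder")

    if "bands" in cfg:
        if band is None:
            raise InvalidInputError(
                f"{name} defines bands {sorted(cfg['bands'])}; pass band="
            )
        band = band.upper()
        if band not in cfg["bands"]:
            raise InvalidInputError(f"{name}: no band {band!r} (have {sorted(cfg['bands'])})")
        bc = cfg["bands"][band]
        mw = float(bc["mw_freq_GHz"])
        linewidth = float(bc["linewidth_G"])
        grid = _parse_grid(bc.get("grid"))
        j_star = bc.get("j_star", cfg.get("j_star"))
        shf_levels = bc.get("shf_levels", cfg.get("shf_levels"))
    else:
        mw = float(cfg["mw_freq_GHz"])
        linewidth = float(cfg["linewidth"])
        grid = _parse_grid(cfg.get("grid"))
        j_star = cfg.get("j_star")
        shf_levels = cfg.get("shf_levels")

    g_raw = cfg["g"]
    system = SpinSystem(
        g=tuple(g_raw) if isinstance(g_raw, (list, tuple)) else float(g_raw),
        nuclei=_parse_nuclei(cfg.get("nuclei", [])),
        lineshape=str(cfg.get("lineshape", "gaussian")),
        linewidth=linewidth,
        linewidth_convention=str(
            cfg.get("linewidth_convention", "gaussian-fwhm-of-absorption")
        ),
        name=name,
    )
    return SystemConfig(
        system=system,
        kind=kind,
        mw_freq_GHz=mw,
        grid=grid,
        j_star=int(j_star) if j_star is not None else None,
        shf_levels=tuple(int(j) for j in shf_levels) if shf_levels else None,
        band=band,
        name=name,
    )


def simulate_system(
    source: str | Path, band: str | None = None, n_orient: int = 1024
) -> Spectrum:
    """Simulate a configured system; dispatches on its ``kind``."""
    cfg = load_system(source, band=band)
    if cfg.kind == "axial_powder":
        spec = simulate_axial_powder(
            cfg.system, cfg.mw_freq_GHz, grid=cfg.grid, n_orient=n_orient
        )
    else:
        spec = simulate_isotropic(cfg.system, cfg.mw_freq_GHz, grid=cfg.grid)
    spec.meta["system"] = cfg.name
    if cfg.band:
        spec.meta["band"] = cfg.band
    if cfg.j_star is not None:
        spec.meta["recommended_j_star"] = cfg.j_star
    return spec
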