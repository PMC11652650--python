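"""Pipeline configuration: schema, defaults, YAML round-trip.

One flat YAML file drives the whole workflow. Unknown keys are rejected
(with their key path) rather than ignored, so a typo never silently
falls back to a default. Omitted keys take the workflow's standard
values: 440 pseudo-absences, k = 10 environmental clusters, 5-fold CV
repeated 10 times, the fixed importance seed list
[11, 17, 22, 34, 54, 68, 96, 108, 224, 312], a final forest of 500
trees with mtry 9, 0.1-wide HSI bins and a suitable range of 0.6–0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .sdm_model import IMPORTANCE_SEEDS, MTRY_GRID, NTREE_GRID
from .synthetic import LandscapeConfig, LayerSpec, default_layer_specs

__all__ = ["PipelineConfig", "validate_config", "load_config"]


@dataclass
class PseudoAbsenceSettings:
    k: int = 10
    n: int = 440
    policy: str = "cluster_exclusion"  # or "distance_threshold"
    distance_quantile: float = 0.75


@dataclass
class ModelSettings:
    tune: bool = True
    ntree_grid: tuple[int, ...] = NTREE_GRID
    mtry_grid: tuple[int, ...] = MTRY_GRID
    folds: int = 5
    repeats: int = 10
    seeds: tuple[int, ...] = IMPORTANCE_SEEDS
    ntree: int = 500  # used when tune is off; otherwise overridden by the OOB best
    mtry: int = 9


@dataclass
class SuitabilitySettings:
    bin_width: float = 0.1
    suitable_lo: float = 0.6
    suitable_hi: float = 0.9
    area_mode: str = "geographic"


@dataclass
class FileInputs:
    layers: dict[str, str] = field(default_factory=dict)  # name -> raster path
    presences: str = ""
    reference: str = ""  # optional binary reference map for accuracy


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "files"
    seed: int = 0
    output_dir: str = "results/run"
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    files: FileInputs = field(default_factory=FileInputs)
    pseudo_absence: PseudoAbsenceSettings = field(default_factory=PseudoAbsenceSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    suitability: SuitabilitySettings = field(default_factory=SuitabilitySettings)

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be 'synthetic' or 'files', got {self.mode!r}")
        if self.mode == "files":
            missing = [p for p in [*self.files.layers.values(), self.files.presences] if p and not Path(p).exists()]
            if not self.files.layers or not self.files.presences:
                raise ValueError("file mode requires files.layers and files.presences")
            if missing:
                raise FileNotFoundError(f"input file(s) not found: {missing}")
        else:
            self.landscape.validate()
        if self.model.folds < 2:
            raise ValueError(f"model.folds must be >= 2, got {self.model.folds}")
        if self.model.repeats < 1:
            raise ValueError("model.repeats must be >= 1")
        if len(self.model.seeds) == 0:
            raise ValueError("model.seeds must be non-empty")
        if self.pseudo_absence.k < 2:
            raise ValueError("pseudo_absence.k must be >= 2")
        if self.pseudo_absence.n < 1:
            raise ValueError("pseudo_absence.n must be >= 1")
        if self.pseudo_absence.policy not in ("cluster_exclusion", "distance_threshold"):
            raise ValueError(f"unknown pseudo-absence policy {self.pseudo_absence.policy!r}")
        if self.suitability.area_mode not in ("geographic", "planar"):
            raise ValueError("suitability.area_mode must be 'geographic' or 'planar'")
        return self

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "pseudo_absence": asdict(self.pseudo_absence),
            "model": {**asdict(self.model), "ntree_grid": list(self.model.ntree_grid),
                      "mtry_grid": list(self.model.mtry_grid), "seeds": list(self.model.seeds)},
            "suitability": asdict(self.suitability),
        }
        if self.mode == "files":
            d["files"] = asdict(self.files)
        else:
            lc = self.landscape
            d["landscape"] = {
                "extent": list(lc.extent),
                "resolutions": dict(lc.resolutions),
                "layers": {
                    name: {"group": s.group, "vmin": s.vmin, "vmax": s.vmax,
                           "length_scale": s.length_scale}
                    for name, s in lc.layer_specs.items()
                },
                "suitability_coefficients": dict(lc.suitability_coefficients),
                "intercept": lc.intercept,
                "n_presence": lc.n_presence,
                "derive_terrain": lc.derive_terrain,
            }
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def _parse_landscape(raw: dict, master_seed: int) -> LandscapeConfig:
    _check_keys(
        raw,
        {"extent", "resolutions", "layers", "suitability_coefficients",
         "intercept", "n_presence", "derive_terrain"},
        "landscape",
    )
    kwargs: dict = {"seed": master_seed}
    if "extent" in raw:
        kwargs["extent"] = tuple(float(v) for v in raw["extent"])
    if "resolutions" in raw:
        kwargs["resolutions"] = {k: float(v) for k, v in raw["resolutions"].items()}
    layers = raw.get("layers", "default")
    if layers == "default":
        kwargs["layer_specs"] = default_layer_specs()
    elif isinstance(layers, list):  # named subset of the default set
        defaults = default_layer_specs()
        bad = [n for n in layers if n not in defaults]
        if bad:
            raise ValueError(f"landscape.layers names not in the default set: {bad}")
        kwargs["layer_specs"] = {n: defaults[n] for n in layers}
    elif isinstance(layers, dict):
        specs = {}
        for name, spec in layers.items():
            _check_keys(spec, {"group", "vmin", "vmax", "length_scale"}, f"landscape.layers.{name}")
            specs[name] = LayerSpec(
                group=spec["group"],
                vmin=float(spec["vmin"]),
                vmax=float(spec["vmax"]),
                length_scale=float(spec.get("length_scale", 0.1)),
            )
        kwargs["layer_specs"] = specs
    else:
        raise ValueError("landscape.layers must be 'default', a name list or a mapping")
    for key in ("suitability_coefficients", "intercept", "n_presence", "derive_terrain"):
        if key in raw:
            kwargs[key] = raw[key]
    return LandscapeConfig(**kwargs)


def parse_config(raw: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a plain dict."""
    _check_keys(
        raw,
        {"mode", "seed", "output_dir", "landscape", "files",
         "pseudo_absence", "model", "suitability"},
        "<root>",
    )
    cfg = PipelineConfig(
        mode=raw.get("mode", "synthetic"),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results/run")),
    )
    if "landscape" in raw:
        cfg.landscape = _parse_landscape(raw["landscape"], cfg.seed)
    else:
        cfg.landscape = LandscapeConfig(seed=cfg.seed)
    if "files" in raw:
        _check_keys(raw["files"], {"layers", "presences", "reference"}, "files")
        cfg.files = FileInputs(
            layers=dict(raw["files"].get("layers", {})),
            presences=raw["files"].get("presences", ""),
            reference=raw["files"].get("reference", ""),
        )
    if "pseudo_absence" in raw:
        _check_keys(raw["pseudo_absence"], {"k", "n", "policy", "distance_quantile"}, "pseudo_absence")
        cfg.pseudo_absence = PseudoAbsenceSettings(**raw["pseudo_absence"])
    if "model" in raw:
        _check_keys(
            raw["model"],
            {"tune", "ntree_grid", "mtry_grid", "folds", "repeats", "seeds", "ntree", "mtry"},
            "model",
        )
        m = dict(raw["model"])
        for key in ("ntree_grid", "mtry_grid", "seeds"):
            if key in m:
                m[key] = tuple(int(v) for v in m[key])
        cfg.model = ModelSettings(**m)
    if "suitability" in raw:
        _check_keys(
            raw["suitability"],
            {"bin_width", "suitable_lo", "suitable_hi", "area_mode"},
            "suitability",
        )
        cfg.suitability = SuitabilitySettings(**raw["suitability"])
    return cfg.validate()


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and validate a YAML pipeline config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return parse_config(raw)


load_config = validate_config
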