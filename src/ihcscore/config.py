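"""Run configuration: defaults, key-value config file parsing, validation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .exceptions import ConfigError
from . import scoring
from .stain_separation import StainMatrix


@dataclass(frozen=True)
class RunConfig:
    stain_matrix: str = "hdab"  # preset name or path to a matrix file
    zone_bounds: tuple[int, int, int, int] = scoring.DEFAULT_ZONE_BOUNDS
    dominance_threshold: float = scoring.DEFAULT_DOMINANCE_THRESHOLD
    stained_area_threshold: int = scoring.DEFAULT_STAINED_AREA_THRESHOLD
    rounding: str = "half_up"  # or "half_down"
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)
    estimate_background: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def resolve_stains(self) -> StainMatrix:
        if self.stain_matrix.lower() == "hdab":
            return StainMatrix.preset("hdab")
        return StainMatrix.from_file(self.stain_matrix)

    def rounding_fn(self):
        if self.rounding == "half_up":
            return scoring.round_half_up
        if self.rounding == "half_down":
            return lambda x: int(-scoring.round_half_up(-x))
        raise ConfigError(f"rounding: unknown mode {self.rounding!r}")


def _parse_scalar(s: str):
    s = s.strip()
    if s.lower() in ("true", "false"):
        return s.lower() == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def parse_config_text(text: str) -> dict:
    """Parse ``key = value`` lines; '#' starts a comment; commas make tuples."""
    out: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        value = value.strip()
        if "," in value:
            out[key.strip()] = tuple(_parse_scalar(v) for v in value.split(","))
        else:
            out[key.strip()] = _parse_scalar(value)
    return out


def validate_config(options: dict | None = None) -> RunConfig:
    """Fill defaults, coerce and validate; raise ConfigError naming the field."""
    cfg = RunConfig()
    options = dict(options or {})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(options) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    if "zone_bounds" in options:
        zb = options["zone_bounds"]
        if isinstance(zb, str):
            zb = tuple(int(v) for v in zb.replace("/", ",").split(","))
        zb = tuple(int(v) for v in zb)
        options["zone_bounds"] = zb
    if "background" in options:
        bg = options["background"]
        if not isinstance(bg, tuple):
            bg = (float(bg),) * 3
        options["background"] = tuple(float(v) for v in bg)
    cfg = replace(cfg, **options)

    zb = cfg.zone_bounds
    if len(zb) != 4 or any(not 0 <= v <= 255 for v in zb) or list(zb) != sorted(set(zb)):
        raise ConfigError(f"zone_bounds: must be 4 strictly increasing integers in [0,255], got {zb}")
    if not 0.0 < cfg.dominance_threshold < 1.0:
        raise ConfigError(f"dominance_threshold: must lie in (0, 1), got {cfg.dominance_threshold}")
    if not 0 <= cfg.stained_area_threshold <= zb[3]:
        raise ConfigError(
            f"stained_area_threshold: must lie in [0, exclusion cutoff {zb[3]}], "
            f"got {cfg.stained_area_threshold}"
        )
    if cfg.rounding not in ("half_up", "half_down"):
        raise ConfigError(f"rounding: unknown mode {cfg.rounding!r}")
    if any(not 0 < b <= 255 for b in cfg.background):
        raise ConfigError(f"background: channel levels must lie in (0, 255], got {cfg.background}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(parse_config_text(fh.read()))
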