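"""Registry of docking programs and cavity-detection tools.

Each docking program carries a score polarity: energy-like scores (Vina,
PLANTS, GalaxyDock3) are better when lower; ZDOCK's shape-complementarity
score is better when higher. The registry is the single source of truth for
program names, display names used in feature columns, and polarity, and is
extensible: registering a new program makes the voxelizer emit its feature
columns automatically.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ProgramSpec:
    """One docking program: its canonical key, feature display name, and
    whether lower scores are better (energy-like) or higher (similarity-like)."""

    key: str
    display: str
    lower_is_better: bool

    def better(self, a: float, b: float) -> bool:
        """True if score ``a`` beats score ``b`` under this program's polarity."""
        return a < b if self.lower_is_better else a > b

    def best(self, scores):
        """Best score among finite entries, respecting polarity."""
        return min(scores) if self.lower_is_better else max(scores)


@dataclass(frozen=True)
class CavityToolSpec:
    """One cavity-detection tool and its display name for feature columns."""

    key: str
    display: str


PROGRAMS: dict[str, ProgramSpec] = {
    "vina": ProgramSpec("vina", "vina", lower_is_better=True),
    "plants": ProgramSpec("plants", "plants", lower_is_better=True),
    "galaxydock": ProgramSpec("galaxydock", "GalaxyDock", lower_is_better=True),
    "zdock": ProgramSpec("zdock", "zdock", lower_is_better=False),
}

CAVITY_TOOLS: dict[str, CavityToolSpec] = {
    "fpocket": CavityToolSpec("fpocket", "Fpocket"),
    "p2rank": CavityToolSpec("p2rank", "P2Rank"),
}

#: Every producer that may appear in a ProgramReport failures list.
ALL_PRODUCERS: tuple[str, ...] = tuple(PROGRAMS) + tuple(CAVITY_TOOLS)


def register_program(spec: ProgramSpec) -> None:
    """Add a docking program to the registry (idempotent for identical specs)."""
    existing = PROGRAMS.get(spec.key)
    if existing is not None and existing != spec:
        raise ValueError(f"program {spec.key!r} already registered with different spec")
    PROGRAMS[spec.key] = spec


def register_cavity_tool(spec: CavityToolSpec) -> None:
    existing = CAVITY_TOOLS.get(spec.key)
    if existing is not None and existing != spec:
        raise ValueError(f"cavity tool {spec.key!r} already registered with different spec")
    CAVITY_TOOLS[spec.key] = spec
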