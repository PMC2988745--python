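"""Growth-medium definitions.

A medium maps extracellular metabolite ids to maximum uptake rates in
mmol·gDW⁻¹·h⁻¹.  It defines the network boundary for both the
reachability audit (medium species seed the traversal) and flux balance
analysis (each medium species' exchange reaction gets lower bound
``-uptake``; uptake is negative flux by convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .core import Model, external_compartments

__all__ = ["Medium", "MediumError", "read_medium_tsv", "read_medium_json"]


class MediumError(ValueError):
    """Medium is inconsistent with the model; message names the offender."""


@dataclass
class Medium:
    uptake: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for mid, rate in self.uptake.items():
            if rate < 0:
                raise MediumError(f"uptake rate for {mid} must be >= 0, got {rate}")

    def validate(self, model: Model) -> None:
        """Every medium species must exist and sit outside the cell."""
        ext = external_compartments(model)
        for mid in self.uptake:
            met = model.metabolites.get(mid)
            if met is None:
                raise MediumError(f"medium metabolite {mid} not present in model {model.id}")
            if not met.is_boundary and met.compartment not in ext:
                raise MediumError(
                    f"medium metabolite {mid} is not extracellular or boundary "
                    f"(compartment {met.compartment!r})"
                )

    def to_tsv(self) -> str:
        lines = ["metabolite\tmax_uptake"]
        lines += [f"{m}\t{r:g}" for m, r in sorted(self.uptake.items())]
        return "\n".join(lines) + "\n"


def read_medium_tsv(path) -> Medium:
    """Two-column TSV: metabolite id, max uptake rate.  '#' comments allowed."""
    uptake: dict[str, float] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.lower().startswith("metabolite"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise MediumError(f"{path}:{ln}: expected two columns, got {len(parts)}")
            try:
                uptake[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise MediumError(f"{path}:{ln}: bad uptake rate {parts[1]!r}") from exc
    return Medium(uptake)


def read_medium_json(path) -> Medium:
    """JSON object mapping metabolite id to max uptake rate."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise MediumError(f"{path}: expected a JSON object of id -> rate")
    return Medium({str(k): float(v) for k, v in data.items()})
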