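"""Run logs and human/machine-readable barrier reports.

Every solve produces a :class:`RunLog` carrying all the intermediate
quantities (workload W, exposure-rate constant Gamma, f-factor, distance d,
unshielded dose D, occupancy O, required transmission T, thickness x) with
explicit units, so the calculation can be reproduced by hand from the
report alone.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .dose import BarrierSolution
from .errors import DomainError


@dataclass(frozen=True)
class RunLog:
    """Everything needed to reproduce one solve by hand."""

    timestamp: str
    version: str
    config_echo: dict
    intermediates: dict  # name -> (value, unit)
    warnings: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def create(cls, config_echo: dict, intermediates: dict, warnings=()) -> "RunLog":
        return cls(
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
            version=__version__,
            config_echo=config_echo,
            intermediates=intermediates,
            warnings=tuple(warnings),
        )


def solution_to_dict(solution: BarrierSolution, log: RunLog) -> dict:
    return {
        "solution": asdict(solution),
        "log": asdict(log),
    }


def render_report(solution: BarrierSolution, log: RunLog, format: str = "text") -> str:
    """Render a barrier solution as text, JSON or CSV.

    The text format walks the full arithmetic chain; the JSON format
    round-trips losslessly through :func:`json.loads`.
    """
    if format == "json":
        return json.dumps(solution_to_dict(solution, log), indent=2)
    if format == "csv":
        import csv as _csv

        buf = io.StringIO()
        writer = _csv.writer(buf)
        writer.writerow(["quantity", "value", "unit"])
        for name, (value, unit) in log.intermediates.items():
            writer.writerow([name, value, unit])
        writer.writerow(["required_transmission", solution.required_transmission, ""])
        writer.writerow(["required_thickness", solution.required_thickness, "mm"])
        writer.writerow(["material", solution.material, ""])
        return buf.getvalue()
    if format != "text":
        raise DomainError(f"Unknown report format {format!r}; use text, json or csv")

    lines = [
        f"nmshield {log.version} barrier report ({log.timestamp})",
        "",
        "Inputs:",
    ]
    for key, value in log.config_echo.items():
        lines.append(f"  {key}: {value}")
    lines += ["", "Calculation chain:"]
    for name, (value, unit) in log.intermediates.items():
        if isinstance(value, float):
            lines.append(f"  {name} = {value:.6g} {unit}".rstrip())
        else:
            lines.append(f"  {name} = {value} {unit}".rstrip())
    lines += [
        "",
        f"Required transmission T = {solution.required_transmission:.4g}",
        f"Required {solution.material} thickness x = "
        f"{solution.required_thickness:.3g} mm",
    ]
    if solution.decay_correction_applied:
        lines.append("Note: workload includes session-averaged decay correction.")
    for w in solution.warnings:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
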