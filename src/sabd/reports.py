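"""Report emission: plain tables, CSV and JSON for results objects.

Table mode rounds probabilities to 3 decimals and expected sample sizes
to 1 decimal (the conventional reporting precision for two-stage design
tables); CSV and JSON carry full precision and round-trip losslessly.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from typing import Any

__all__ = ["result_to_dict", "render_table", "write_report"]


def _jsonable(v: Any):
    """Coerce NumPy scalars to native Python numbers for JSON output."""
    if hasattr(v, "item"):
        return v.item()
    raise TypeError(f"cannot serialise {type(v).__name__}")


def _flatten(prefix: str, value: Any, out: dict[str, Any]) -> None:
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        for f in dataclasses.fields(value):
            _flatten(
                f"{prefix}{f.name}." if prefix else f"{f.name}.",
                getattr(value, f.name),
                out,
            )
        return
    if isinstance(value, dict):
        for k, v in value.items():
            out[f"{prefix}{k}"] = v
        return
    out[prefix.rstrip(".")] = value


def result_to_dict(result: Any) -> dict[str, Any]:
    """Flatten a result dataclass into scalar columns."""
    out: dict[str, Any] = {}
    _flatten("", result, out)
    return out


def _fmt(key: str, v: Any) -> str:
    if isinstance(v, float):
        if "ess" in key.lower():
            return f"{v:.1f}"
        return f"{v:.3f}"
    return str(v)


def render_table(result: Any) -> str:
    """One aligned key/value row block per result."""
    d = result_to_dict(result)
    width = max(len(k) for k in d)
    lines = [f"{k:<{width}}  {_fmt(k, v)}" for k, v in d.items()]
    return "\n".join(lines)


def write_report(result: Any, fmt: str = "table", path: str | None = None) -> str:
    """Emit a result as ``table``, ``csv`` or ``json``; returns the text.

    If ``path`` is given the text is also written there.
    """
    if fmt == "table":
        text = render_table(result) + "\n"
    elif fmt == "json":
        text = json.dumps(result_to_dict(result), indent=2, default=_jsonable) + "\n"
    elif fmt == "csv":
        d = result_to_dict(result)
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(d))
        writer.writeheader()
        writer.writerow(d)
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}; choose table, csv or json")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
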