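"""Run output: CSV trajectories, provenance record, file manifest."""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .spread import SimulationResult

__all__ = ["write_run"]


def _package_version() -> str:
    try:
        return version("panicwave")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_run(
    result: SimulationResult | pd.DataFrame | dict[str, pd.DataFrame],
    config: RunConfig,
    out_dir: str | Path,
) -> list[Path]:
    """Write run outputs plus a provenance record; return the file manifest.

    ``result`` may be a single trajectory, a plain table, or a mapping of
    named tables (sweep outputs).  CSVs are comma-separated UTF-8 with a
    header row; re-running the same config and seed reproduces them
    byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    if isinstance(result, SimulationResult):
        tables = {"trajectory": result.frame}
    elif isinstance(result, pd.DataFrame):
        tables = {"table": result}
    else:
        tables = dict(result)
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        manifest.append(path)

    provenance = {
        "config": config.model_dump(),
        "seed": config.seed,
        "package_version": _package_version(),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    manifest.append(prov_path)

    manifest_path = out / "manifest.txt"
    manifest_path.write_text("".join(f"{p.name}\n" for p in manifest))
    manifest.append(manifest_path)
    return manifest
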