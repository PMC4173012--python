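"""TSV readers/writers, replicate consensus and the run manifest.

All tabular formats are plain tab-separated text with a header row:

* peak table: ``id  mz  rt  intensity`` (``id`` optional; the m/z, RT and
  intensity columns are matched case-insensitively against the common
  dialects ``mz``/``mass``/``m/z``, ``rt``/``retention_time`` and
  ``intensity``/``area``);
* formula database: ``id  name  formula``;
* adduct list: ``rule  charge``;
* truth file: ``formula_id  present`` (0/1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .chem import AdductRule, Formula, parse_adduct_rule, parse_formula
from .posterior import PosteriorSummary
from .sampler import Peak

__all__ = [
    "RunConfig",
    "read_peaks",
    "write_peaks",
    "read_formula_db",
    "write_formula_db",
    "read_adducts",
    "write_adducts",
    "read_truth",
    "write_truth",
    "consensus_peaks",
    "write_annotations",
    "write_presence",
    "write_manifest",
]

# accepted header spellings, matched case-insensitively, first hit wins
_COLUMN_ALIASES = {
    "mz": ("mz", "mass", "m/z"),
    "rt": ("rt", "retention_time"),
    "intensity": ("intensity", "area"),
}


@dataclass
class RunConfig:
    """Resolved configuration of one annotation run."""

    peaks_path: str
    db_path: str
    adducts_path: str
    out_dir: str
    ppm: float = 3.0
    alpha: float = 1.0
    iterations: int = 1000
    burn_in: int = 200
    seed: int = 0
    prefilter: float = 0.0
    support_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    rt_minutes: bool = False


class TableFormatError(ValueError):
    """Raised when a TSV does not match the documented schema."""


def _resolve_columns(columns) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    resolved = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
        else:
            raise TableFormatError(
                f"missing required column {canon!r} "
                f"(accepted spellings: {', '.join(aliases)})"
            )
    return resolved


def read_peaks(path: str | Path, rt_minutes: bool = False) -> list[Peak]:
    """Read an aligned feature table.  Malformed rows are reported with their
    (1-based, header-inclusive) line numbers."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    cols = _resolve_columns(df.columns)
    id_col = next((c for c in df.columns if str(c).strip().lower() == "id"), None)
    peaks = []
    errors = []
    for row_idx, row in df.iterrows():
        line = int(row_idx) + 2
        pid = str(row[id_col]) if id_col is not None else f"peak_{row_idx}"
        try:
            mz = float(row[cols["mz"]])
            rt = float(row[cols["rt"]])
            w = float(row[cols["intensity"]])
        except (TypeError, ValueError):
            errors.append(f"line {line}: non-numeric cell")
            continue
        if rt_minutes:
            rt *= 60.0
        try:
            peaks.append(Peak(pid, mz, rt, w))
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise TableFormatError(f"{path}: " + "; ".join(errors))
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in peaks],
            "mz": [p.mz for p in peaks],
            "rt": [p.rt for p in peaks],
            "intensity": [p.intensity for p in peaks],
        }
    ).to_csv(path, sep="\t", index=False)


def read_formula_db(path: str | Path) -> tuple[list[str], list[str], list[Formula]]:
    """Read the formula database: columns ``id``, ``name``, ``formula``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "name", "formula"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    ids = df["id"].tolist()
    names = df["name"].tolist()
    formulas = [parse_formula(s) for s in df["formula"]]
    return ids, names, formulas


def write_formula_db(
    ids: list[str], names: list[str], formulas: list[Formula], path: str | Path
) -> None:
    pd.DataFrame(
        {"id": ids, "name": names, "formula": [str(f) for f in formulas]}
    ).to_csv(path, sep="\t", index=False)


def read_adducts(path: str | Path) -> list[AdductRule]:
    """Read the adduct list: columns ``rule``, ``charge``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("rule", "charge"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return [
        parse_adduct_rule(str(r), int(c)) for r, c in zip(df["rule"], df["charge"])
    ]


def write_adducts(adducts: list[AdductRule], path: str | Path) -> None:
    pd.DataFrame(
        {"rule": [a.name for a in adducts], "charge": [a.charge for a in adducts]}
    ).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> dict[str, bool]:
    df = pd.read_csv(path, sep="\t", dtype={"formula_id": str})
    for col in ("formula_id", "present"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return {str(f): bool(int(p)) for f, p in zip(df["formula_id"], df["present"])}


def write_truth(truth: dict[str, bool], path: str | Path) -> None:
    pd.DataFrame(
        {"formula_id": list(truth), "present": [int(v) for v in truth.values()]}
    ).to_csv(path, sep="\t", index=False)


def consensus_peaks(replicate_tables: list[list[Peak]]) -> list[Peak]:
    """One consensus peak per id: mean m/z, RT and intensity over the
    replicates in which the id appears (inputs are assumed pre-aligned, so a
    shared id denotes the same feature)."""
    if not replicate_tables:
        raise ValueError("need at least one replicate table")
    acc: dict[str, list[tuple[float, float, float]]] = {}
    order: list[str] = []
    for table in replicate_tables:
        for p in table:
            if p.id not in acc:
                acc[p.id] = []
                order.append(p.id)
            acc[p.id].append((p.mz, p.rt, p.intensity))
    out = []
    for pid in order:
        rows = acc[pid]
        n = len(rows)
        out.append(
            Peak(
                pid,
                sum(r[0] for r in rows) / n,
                sum(r[1] for r in rows) / n,
                sum(r[2] for r in rows) / n,
            )
        )
    return out


def write_annotations(
    summary: PosteriorSummary,
    library,
    path: str | Path,
) -> None:
    """Peak annotation table: one row per (peak, formula, adduct, isotope)
    candidate with the three probability variants."""
    rows = []
    ids = library.formula_ids or [str(m) for m in range(library.n_formulas)]
    for pid in summary.peak_prior:
        keys = (
            set(summary.peak_prior.get(pid, {}))
            | set(summary.peak_posterior.get(pid, {}))
            | set(summary.peak_filtered.get(pid, {}))
        )
        for m, a, i in sorted(keys):
            rows.append(
                {
                    "peak_id": pid,
                    "formula_id": ids[m],
                    "adduct": library.adducts[a].name,
                    "isotope_index": i,
                    "prob_prior": summary.peak_prior.get(pid, {}).get((m, a, i), 0.0),
                    "prob_posterior": summary.peak_posterior.get(pid, {}).get(
                        (m, a, i), 0.0
                    ),
                    "prob_filtered": summary.peak_filtered.get(pid, {}).get(
                        (m, a, i), 0.0
                    ),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "formula_id",
            "adduct",
            "isotope_index",
            "prob_prior",
            "prob_posterior",
            "prob_filtered",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_presence(summary: PosteriorSummary, library, path: str | Path) -> None:
    """Formula presence table: one row per formula with the presence
    probability at each support level."""
    ids = library.formula_ids or [str(m) for m in range(library.n_formulas)]
    names = library.formula_names or [str(f) for f in library.formulas]
    rows = []
    for m in range(library.n_formulas):
        row = {"formula_id": ids[m], "name": names[m]}
        for l in summary.levels:
            row[f"prob_l{l}"] = summary.presence.get(m, {}).get(l, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(config: RunConfig, hyper, path: str | Path) -> None:
    """JSON run manifest: configuration, hyperparameters and input checksums,
    enough to re-run the analysis byte-identically."""
    manifest = {
        "config": asdict(config),
        "hyperparameters": {
            k: v for k, v in vars(hyper).items() if not isinstance(v, list) or v
        },
        "input_checksums": {
            name: _file_checksum(p)
            for name, p in (
                ("peaks", config.peaks_path),
                ("formula_db", config.db_path),
                ("adducts", config.adducts_path),
            )
            if Path(p).exists()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
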