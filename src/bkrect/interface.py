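"""Configuration, file I/O, packaged fixtures and report rendering.

Trace files are the CSV/ATF dialects written by
:mod:`bkrect.synthetic_data`; every written patch carries a JSON sidecar
with the protocol, preset name, seed and occupancy weights, so any output
is reproducible from config + seed alone.  The packaged fixtures are the
transcribed evidence table, the synthetic β2 sequence and the preset
catalog, letting the whole pipeline run offline.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError
from .pairing import EvidenceTable, PairingResult
from .synthetic_data import ChannelPreset, SimulatedPatch, VoltageProtocol

__all__ = [
    "RunConfig",
    "read_traces",
    "render_report",
    "fixture_path",
    "load_evidence_table",
    "load_beta2_sequence",
    "load_preset_catalog",
]


# ---------------------------------------------------------------------------
# run configuration (TOML round trip)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Parameters of one simulation/analysis run.

    Serialized as flat TOML; ``from_toml(cfg.to_toml())`` is lossless, and
    ``config_hash`` is echoed into reports so artifacts can be traced back.
    """

    preset: str = "WT-beta2"
    seed: int = 1
    n_patches: int = 12
    noise_sd: float = 0.02
    R_alpha: float = 1.12
    alpha: float = 0.05
    trace_format: str = "csv"
    out_dir: str = "bkrect-out"
    sample_interval: float = 0.05
    test_pulse_dur: float = 200.0
    tail_level_dur: float = 20.0

    def to_toml(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, int):
                lines.append(f"{f.name} = {v}")
            else:
                lines.append(f"{f.name} = {float(v)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        data = tomllib.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.from_toml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trace reading
# ---------------------------------------------------------------------------

def _parse_level(col: str) -> float:
    if not (col.startswith("V_") and col.endswith("mV")):
        raise FormatError(f"unrecognized trace column {col!r}")
    return float(col[2:-2])


def read_traces(path: str | Path,
                protocol: VoltageProtocol | None = None) -> SimulatedPatch:
    """Read a CSV or ATF trace family back into a patch.

    CSV round-trips bit-identically.  The protocol comes from the JSON
    sidecar written alongside the traces, or from the ``protocol``
    argument when the sidecar is absent.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".atf" or text.startswith("ATF"):
        names, data, meta = _parse_atf(text)
    else:
        names, data, meta = _parse_csv(text)
    if names[0] != "time_ms":
        raise FormatError("first trace column must be time_ms")
    sidecar = Path(str(path) + ".json")
    weights = np.array([1.0, 0, 0, 0, 0])
    preset_name, seed = meta.get("preset", path.stem), meta.get("seed")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        protocol = VoltageProtocol(**{
            k: tuple(v) if k == "levels" else v
            for k, v in info["protocol"].items()})
        weights = np.array(info["occupancy_weights"])
        preset_name = info.get("preset", preset_name)
        seed = info.get("seed", seed)
    if protocol is None:
        raise FormatError(
            f"{path}: no protocol sidecar found; pass protocol= explicitly")
    currents = {_parse_level(c): data[:, i]
                for i, c in enumerate(names) if i > 0}
    return SimulatedPatch(
        preset_name=preset_name, protocol=protocol, time=data[:, 0],
        currents=currents, seed=None if seed is None else int(seed),
        occupancy_weights=weights,
    )


def _parse_csv(text: str):
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty trace file")
    names = lines[0].split(",")
    rows = []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != len(names):
            raise FormatError("ragged CSV trace row")
        rows.append([float(x) for x in parts])
    return names, np.array(rows), {}


def _parse_atf(text: str):
    lines = text.splitlines()
    if not lines or lines[0].split("\t")[0] != "ATF":
        raise FormatError("not an Axon Text File: bad magic")
    try:
        n_header, n_cols = (int(x) for x in lines[1].split("\t"))
    except (ValueError, IndexError) as e:
        raise FormatError("malformed ATF dimension line") from e
    meta: dict[str, str] = {}
    for ln in lines[2: 2 + n_header]:
        record = ln.strip().strip('"')
        if "=" in record:
            k, v = record.split("=", 1)
            meta[k] = v
    names = [c.strip('"') for c in lines[2 + n_header].split("\t")]
    if len(names) != n_cols:
        raise FormatError("ATF column count mismatch")
    rows = []
    for ln in lines[3 + n_header:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise FormatError("ragged ATF data row")
        rows.append([float(x) for x in parts])
    if meta.get("seed") in ("None", ""):
        meta.pop("seed")
    return names, np.array(rows), meta


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def fixture_path(name: str) -> Path:
    p = resources.files("bkrect") / "data" / name
    with resources.as_file(p) as fp:
        return Path(fp)


def load_evidence_table() -> EvidenceTable:
    """The transcribed per-mutant evidence table (R_eq, q, Δq_e)."""
    return EvidenceTable.from_csv(fixture_path("evidence_table.csv"))


def load_beta2_sequence() -> str:
    """Synthetic β2 base sequence (see the FASTA header for provenance)."""
    rec = next(SeqIO.parse(fixture_path("beta2_loop_synthetic.fasta"), "fasta"))
    return str(rec.seq)


def load_preset_catalog() -> dict[str, ChannelPreset]:
    """Preset catalog from the packaged TOML (matches
    :func:`bkrect.synthetic_data.make_preset_catalog`)."""
    with open(fixture_path("presets.toml"), "rb") as fh:
        data = tomllib.load(fh)
    return {name: ChannelPreset(name=name, **params)
            for name, params in data.items()}


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _md_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(str(v) for v in rec) + " |"
            for rec in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def render_report(
    result: PairingResult,
    table: EvidenceTable,
    digestion_table: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> str:
    """Markdown report: evidence, verdicts, inferred pairs, digestion."""
    parts = ["# β2-loop disulfide connectivity report", ""]
    if config is not None:
        parts += ["## Run configuration",
                  f"- seed: {config.seed}",
                  f"- config hash: {config.config_hash()}",
                  "", "```toml", config.to_toml().rstrip(), "```", ""]
    parts += ["## Evidence table (mean ± sd, n)", "",
              _md_table(table.to_frame().drop(columns=["source"])), ""]
    tl = pd.DataFrame([asdict_v(v) for v in result.triplet_log])
    parts += ["## Triplet similarity verdicts (one-way ANOVA)", "",
              _md_table(tl), ""]
    if result.charge_log:
        cl = pd.DataFrame([asdict_v(v) for v in result.charge_log])
        cl["labels"] = cl["labels"].map(lambda t: ";".join(t))
        parts += ["## Charge-probe consistency (Welch tests vs WT)", "",
                  _md_table(cl), ""]
    parts += ["## Inferred disulfide pairs", ""]
    for a, b in result.pairs:
        from .pairing import CYSTEINE_MAP
        parts.append(f"- {a}(C{CYSTEINE_MAP[a]})–{b}(C{CYSTEINE_MAP[b]})")
    parts += ["", f"Unpaired: {', '.join(result.unpaired) or 'none'}", ""]
    if digestion_table is not None:
        parts += ["## TEV digestion truth table (±DTT HA-band release)", "",
                  _md_table(digestion_table), ""]
    return "\n".join(parts)


def asdict_v(obj) -> dict:
    from dataclasses import asdict as _as
    d = _as(obj)
    for k, v in d.items():
        if isinstance(v, float):
            d[k] = round(v, 4)
    return d
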