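"""Run configuration: every tunable threshold with its published default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """All thresholds the toolkit applies, with their default values.

    The defaults are the operating points of the published screening
    procedure: the 3% intergenic-overlap cutoff, the ORF-finder minimum
    length, the 60–200 aa candidate screen, the catalog-match rule
    (e-value <= 0.01, identity >= 35%), the PDB-chain mapping rule
    (e-value <= 1e-10, <= 1 mismatch, >= 95% coverage), the two acr
    pinpointing e-value cutoffs and the Monte Carlo iteration count.
    """

    overlap_threshold: float = 0.03
    min_orf_nt: int = 75
    screen_min_aa: int = 60
    screen_max_aa: int = 200
    catalog_evalue: float = 0.01
    catalog_identity: float = 35.0
    pdb_evalue: float = 1e-10
    pdb_mismatch: int = 1
    pdb_coverage: float = 0.95
    acr_evalue_loose: float = 1e-3
    acr_evalue_strict: float = 1e-6
    n_iter: int = 10000
    seed: int = 0

    def items(self) -> list[tuple[str, object]]:
        return [(f.name, getattr(self, f.name)) for f in fields(self)]

    def header_lines(self, tool_version: str) -> list[str]:
        """Comment header serialized into every output so runs are self-describing."""
        lines = [f"# acrkit v{tool_version}"]
        lines += [f"# {k}={v}" for k, v in self.items()]
        return lines

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load key=value overrides from a flat text config file."""
        cfg = cls()
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {raw.strip()!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(cfg, key)
                setattr(cfg, key, type(current)(float(value)) if isinstance(current, int) else type(current)(value))
        return cfg
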