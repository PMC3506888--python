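"""Run configuration shared by the CLI stages.

Every tunable of the pipeline lives here with its documented default, and
every output directory receives a serialized snapshot of the configuration
actually used (the reproducibility contract).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    seed: int = 42
    db_size: int = 10000  # effective database size for calibration e-values
    gap_threshold: float = 0.5  # match-column gap-fraction threshold (strict <)
    pseudocount: float = 1.0
    min_aa: int = 50  # minimum ORF length in codons
    coverage_threshold: float = 0.5  # fragment flag below this profile coverage
    overlap_nt: int = 30  # CDS overlap disqualifying an ORF from intergenic status
    min_reciprocal_overlap: float = 0.5  # annotation-comparison matching rule
    evd_n_random: int = 5000
    genetic_code: int = 11
    keywords: list = field(
        default_factory=lambda: [
            "transposase", "insertion sequence", "resolvase",
            "recombinase", "integrase",
        ]
    )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
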