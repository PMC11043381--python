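"""Machine-readable audit trail of per-SNP filtering decisions.

Every stage that keeps, drops, or rewrites a SNP appends one row here, so
the attrition from raw summary statistics to the final instrument set is
fully accounted for: input count = retained count + logged drops, at every
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class AuditEntry:
    snp_id: str
    stage: str
    action: str  # keep | drop | warn | note
    reason: str


@dataclass
class AuditLog:
    entries: list[AuditEntry] = field(default_factory=list)

    def record(self, snp_id: str, stage: str, action: str, reason: str) -> None:
        self.entries.append(AuditEntry(snp_id, stage, action, reason))

    def drops(self, stage: str | None = None) -> list[AuditEntry]:
        return [
            e
            for e in self.entries
            if e.action == "drop" and (stage is None or e.stage == stage)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.snp_id, e.stage, e.action, e.reason) for e in self.entries],
            columns=["snp_id", "stage", "action", "reason"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
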