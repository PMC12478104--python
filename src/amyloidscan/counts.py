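"""Tidy per-variant read-count tables across selection conditions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reference import VariantId

#: Reasons a read can be excluded during genotyping.
DISCARD_REASONS = (
    "truncated",
    "indel-length",
    "ambiguous-base",
    "premature-stop",
    "multi-substitution",
)


@dataclass
class CountTable:
    """Reads per variant per (ampicillin concentration, replicate).

    ``df`` is tidy with columns ``variant`` (label string), ``position``,
    ``wt_aa``, ``mut_aa``, ``concentration``, ``replicate``, ``count``.
    ``discarded`` tallies excluded reads by reason per condition, so that
    for every condition ``assigned counts + discards == reads processed``.
    """

    df: pd.DataFrame
    discarded: dict[tuple[float, int], dict[str, int]] = field(default_factory=dict)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_mapping(
        cls,
        counts: dict[tuple[VariantId, float, int], int],
        discarded: dict[tuple[float, int], dict[str, int]] | None = None,
    ) -> "CountTable":
        # canonical row order: condition-major, then variant — makes table
        # construction independent of read encounter order
        items = sorted(
            counts.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])
        )
        rows = []
        for (variant, conc, rep), n in items:
            rows.append(
                {
                    "variant": variant.label,
                    "position": variant.position,
                    "wt_aa": variant.wt_aa,
                    "mut_aa": variant.mut_aa,
                    "concentration": float(conc),
                    "replicate": int(rep),
                    "count": int(n),
                }
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "variant", "position", "wt_aa", "mut_aa",
                "concentration", "replicate", "count",
            ],
        )
        return cls(df=df, discarded=discarded or {})

    # -- views ----------------------------------------------------------
    @property
    def concentrations(self) -> list[float]:
        return sorted(self.df["concentration"].unique())

    @property
    def replicates(self) -> list[int]:
        return sorted(self.df["replicate"].unique())

    def totals(self) -> pd.Series:
        """Assigned reads per (concentration, replicate)."""
        return self.df.groupby(["concentration", "replicate"])["count"].sum()

    def matrix(self, replicate: int) -> pd.DataFrame:
        """Variant x concentration count matrix for one replicate (0-filled)."""
        sub = self.df[self.df["replicate"] == replicate]
        return (
            sub.pivot_table(
                index="variant", columns="concentration", values="count",
                aggfunc="sum", fill_value=0,
            )
            .astype(int)
        )

    def variant_counts(self, concentration: float, replicate: int) -> pd.Series:
        sub = self.df[
            (self.df["concentration"] == concentration)
            & (self.df["replicate"] == replicate)
        ]
        return sub.set_index("variant")["count"]

    def reads_processed(self, concentration: float, replicate: int) -> int:
        assigned = int(
            self.df.loc[
                (self.df["concentration"] == concentration)
                & (self.df["replicate"] == replicate),
                "count",
            ].sum()
        )
        dropped = sum(self.discarded.get((concentration, replicate), {}).values())
        return assigned + dropped

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(
            path, sep="\t",
            dtype={"variant": str, "wt_aa": str, "mut_aa": str},
            keep_default_na=False,
        )
        df["position"] = df["position"].astype(int)
        df["concentration"] = df["concentration"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["count"] = df["count"].astype(int)
        return cls(df=df)
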