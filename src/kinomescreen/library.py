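"""Guide library and sample sheet containers with TSV round-trip IO.

The screen's measurement universe is a pooled knockout library: ~4 sgRNAs per
kinase gene plus non-targeting controls (NTCs) carrying a reserved gene label.
Samples are (mouse, stage) sequencing libraries distinguished by PCR barcodes,
each annotated with the host genotype (``WT`` or ``CD8KO``) and the sacrifice
stage (``early``, ``late`` or ``terminal``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

NTC_GENE = "NTC"
GENOTYPES = ("WT", "CD8KO")
STAGES = ("early", "late", "terminal")

_DNA = set("ACGT")


@dataclass(frozen=True)
class GuideLibrary:
    """Guide -> gene map with protospacer sequences and NTC flags.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``guide_id``, ``gene``, ``protospacer``, ``is_ntc``; one row
        per guide, in library order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["guide_id", "gene", "protospacer", "is_ntc"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"guide library missing columns: {missing}")
        if len(t) == 0:
            raise ValueError("guide library is empty")
        if t["guide_id"].duplicated().any():
            dup = t.loc[t["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise ValueError(f"duplicate guide_id in library: {dup!r}")
        if t["protospacer"].duplicated().any():
            dup = t.loc[t["protospacer"].duplicated(), "protospacer"].iloc[0]
            raise ValueError(f"duplicate protospacer in library: {dup!r}")
        bad = ~t["protospacer"].map(lambda s: bool(s) and set(s) <= _DNA)
        if bad.any():
            raise ValueError(
                f"protospacer not uppercase ACGT: {t.loc[bad, 'protospacer'].iloc[0]!r}"
            )
        ntc_rows = t["is_ntc"].astype(bool)
        if (t.loc[ntc_rows, "gene"] != NTC_GENE).any():
            raise ValueError(f"NTC guides must carry the reserved gene label {NTC_GENE!r}")

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def ntc_guide_ids(self) -> pd.Index:
        m = self.table["is_ntc"].astype(bool)
        return pd.Index(self.table.loc[m, "guide_id"])

    def gene_of(self) -> pd.Series:
        """guide_id -> gene, indexed by guide_id."""
        return self.table.set_index("guide_id")["gene"]

    def protospacer_map(self) -> dict[str, str]:
        """protospacer -> guide_id (unique by invariant)."""
        return dict(zip(self.table["protospacer"], self.table["guide_id"]))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GuideLibrary":
        t = pd.read_csv(path, sep="\t", dtype={"guide_id": str, "gene": str, "protospacer": str})
        t["is_ntc"] = t["is_ntc"].astype(bool)
        return cls(t)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: genotype, stage, mouse and PCR barcode.

    ``sample_id`` and ``barcode`` must be unique; genotype and stage are drawn
    from closed vocabularies.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "genotype", "stage", "mouse_id", "barcode"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if len(t) == 0:
            raise ValueError("sample sheet is empty")
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        if t["barcode"].duplicated().any():
            raise ValueError("duplicate barcode in sample sheet")
        lens = t["barcode"].str.len()
        if lens.nunique() > 1:
            raise ValueError("barcodes must all have equal length")
        bad_g = ~t["genotype"].isin(GENOTYPES)
        if bad_g.any():
            raise ValueError(f"unknown genotype {t.loc[bad_g, 'genotype'].iloc[0]!r}")
        bad_s = ~t["stage"].isin(STAGES)
        if bad_s.any():
            raise ValueError(f"unknown stage {t.loc[bad_s, 'stage'].iloc[0]!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    @property
    def barcode_length(self) -> int:
        return int(self.table["barcode"].str.len().iloc[0])

    def barcode_map(self) -> dict[str, str]:
        """barcode -> sample_id."""
        return dict(zip(self.table["barcode"], self.table["sample_id"]))

    def samples_in(self, genotype: str | None = None, stage: str | None = None) -> list[str]:
        t = self.table
        m = pd.Series(True, index=t.index)
        if genotype is not None:
            m &= t["genotype"] == genotype
        if stage is not None:
            m &= t["stage"] == stage
        return list(t.loc[m, "sample_id"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a guide x sample count matrix TSV (guide_id row keys)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="guide_id")
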