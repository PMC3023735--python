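"""Published target-catalog fixtures and tally helpers.

The package ships, as versioned TSV fixtures, the two target catalogs the
originating soybean-seed degradome study printed in full: the validated
cleavage targets of annotated (miRBase) miRNAs and those of the newly
discovered miRNAs. Each row carries the guide miRNA, target gene, its
annotation, confidence class (I-IV), cleavage-signature abundance in TP10M,
the cleavage site(s) on the transcript, and the site region; shared-read
footnote marks are kept in ``mark`` and soybean-specific miRNA families are
flagged in ``specific_family``.

Dual sites like "688/689" (both ends of one scissile region validated) and
short ranges like "93-95" are stored verbatim and parse to multiple
positions of a single target row.
"""

from __future__ import annotations

from importlib import resources
from typing import Callable, Optional, Union

import pandas as pd

__all__ = ["load_fixture", "parse_sites", "summarize_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("known_mirna_targets", "novel_mirna_targets")

_COLUMNS = [
    "mirna",
    "target_gene",
    "mark",
    "annotation",
    "class",
    "abundance_tp10m",
    "cleavage_site",
    "location",
    "specific_family",
]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a shipped catalog ("known_mirna_targets" or "novel_mirna_targets")."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("mirslice.data").joinpath(f"{name}.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False, dtype={"mark": str})
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"fixture {name} has unexpected columns")
    if not df["class"].isin(["I", "II", "III", "IV"]).all():
        raise ValueError("bad class label in fixture")
    if (df["abundance_tp10m"] < 0).any():
        raise ValueError("negative abundance in fixture")
    dup = df.duplicated(subset=["mirna", "target_gene", "cleavage_site"])
    if dup.any():
        raise ValueError("duplicate (miRNA, target, site) rows in fixture")
    return df


def parse_sites(site_field: Union[str, int]) -> list[int]:
    """Expand a cleavage-site field into validated positions.

    "688/689" -> [688, 689]; "93-95" -> [93, 94, 95]; "450" -> [450].
    """
    s = str(site_field)
    if "/" in s:
        return [int(x) for x in s.split("/")]
    if "-" in s:
        a, b = s.split("-")
        return list(range(int(a), int(b) + 1))
    return [int(s)]


def summarize_fixture(
    fixture: pd.DataFrame,
    group_by: Optional[str] = None,
    where: Optional[Callable[[pd.Series], bool]] = None,
) -> Union[int, dict]:
    """Pure tally over catalog rows.

    Without ``group_by`` returns the number of rows passing ``where``; with
    it, a {value: row count} dict. Each row is one target (dual-site rows
    count once).
    """
    df = fixture
    if where is not None:
        df = df[df.apply(where, axis=1)]
    if group_by is None:
        return int(len(df))
    if group_by not in df.columns:
        raise ValueError(f"unknown field {group_by!r}")
    return {k: int(v) for k, v in df.groupby(group_by).size().items()}
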