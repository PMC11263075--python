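"""MedDRA-like term sets for the sexual-dysfunction analysis.

The analysis is driven by a small controlled vocabulary: preferred terms
(PTs), their high-level group term (HLGT), an optional symptom subgroup
(hypersexuality, hyposexuality, erectile dysfunction, ejaculatory
dysfunction), and a flag marking impulse-control-disorder (ICD) related
terms used by the notoriety-bias sensitivity analyses.

The sexual-dysfunction (SD) event set is defined structurally: every PT
whose HLGT is one of the two SD group terms.  A default termset built from
the terms named in the study literature ships with the package; users can
substitute a licensed MedDRA export with the same four columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

#: HLGTs whose member PTs constitute the SD event set.
SD_HLGTS = frozenset(
    {
        "sexual function and fertility disorders",
        "sexual dysfunctions, disturbances and gender identity disorders",
    }
)

SUBGROUPS = (
    "hypersexuality",
    "hyposexuality",
    "erectile_dysfunction",
    "ejaculatory_dysfunction",
)

_VALID_SUBGROUP = frozenset(SUBGROUPS) | {"none"}

_WS = re.compile(r"\s+")


def normalize_pt(name: str) -> str:
    """Case-fold a PT and collapse internal whitespace.

    Spontaneous-report sources are inconsistent about PT casing across
    eras, so every lookup in this package goes through this normalization.
    """
    return _WS.sub(" ", str(name).strip()).lower()


class TermSetError(ValueError):
    """Raised when a term-set file fails validation."""


@dataclass(frozen=True)
class TermSet:
    """A validated PT vocabulary.

    Attributes
    ----------
    pt_names : frozenset of PT strings (normalized).
    hlgt_of : PT -> HLGT.
    subgroup_of : PT -> subgroup label or ``"none"``.
    icd_related : PTs flagged as impulse-control-disorder related.
    """

    pt_names: frozenset = field(default_factory=frozenset)
    hlgt_of: dict = field(default_factory=dict)
    subgroup_of: dict = field(default_factory=dict)
    icd_related: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for pt in self.subgroup_of:
            if pt not in self.pt_names:
                raise TermSetError(f"subgroup mapping for unknown PT {pt!r}")
        for pt in self.icd_related:
            if pt not in self.pt_names:
                raise TermSetError(f"icd flag for unknown PT {pt!r}")
        bad = set(self.subgroup_of.values()) - _VALID_SUBGROUP
        if bad:
            raise TermSetError(f"unknown subgroup labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.pt_names)

    def sd_event_pts(self) -> frozenset:
        """PTs belonging to either of the two SD HLGTs."""
        return frozenset(pt for pt in self.pt_names if self.hlgt_of.get(pt) in SD_HLGTS)

    def subgroup_pts(self, subgroup: str) -> frozenset:
        """Member PTs of one symptom subgroup (subset of the SD event set)."""
        if subgroup not in SUBGROUPS:
            raise KeyError(f"unknown subgroup {subgroup!r}")
        sd = self.sd_event_pts()
        return frozenset(
            pt for pt, g in self.subgroup_of.items() if g == subgroup and pt in sd
        )


def sd_event_pts(ts: TermSet) -> frozenset:
    """Functional alias for :meth:`TermSet.sd_event_pts`."""
    return ts.sd_event_pts()


def load_termset(path) -> TermSet:
    """Read a term-set CSV (columns ``pt,hlgt,subgroup,icd_flag``).

    Duplicate PT rows with conflicting mappings raise :class:`TermSetError`
    naming the PT; exact duplicate rows are tolerated.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"pt", "hlgt", "subgroup", "icd_flag"}
    missing = required - set(df.columns)
    if missing:
        raise TermSetError(f"term-set file missing columns: {sorted(missing)}")
    if df.empty:
        return TermSet()

    df = df.assign(
        pt=df["pt"].map(normalize_pt),
        hlgt=df["hlgt"].map(normalize_pt),
        subgroup=df["subgroup"].str.strip().str.lower(),
        icd_flag=df["icd_flag"].astype(int),
    )
    for pt, grp in df.groupby("pt"):
        if grp[["hlgt", "subgroup", "icd_flag"]].drop_duplicates().shape[0] > 1:
            raise TermSetError(f"conflicting mappings for PT {pt!r}")
    df = df.drop_duplicates("pt")
    return TermSet(
        pt_names=frozenset(df["pt"]),
        hlgt_of=dict(zip(df["pt"], df["hlgt"])),
        subgroup_of={
            pt: sg for pt, sg in zip(df["pt"], df["subgroup"]) if sg != "none"
        }
        | {pt: "none" for pt, sg in zip(df["pt"], df["subgroup"]) if sg == "none"},
        icd_related=frozenset(df.loc[df["icd_flag"] == 1, "pt"]),
    )


def write_termset(ts: TermSet, path) -> Path:
    """Write a TermSet back to the CSV interchange format (round-trips)."""
    rows = [
        {
            "pt": pt,
            "hlgt": ts.hlgt_of.get(pt, ""),
            "subgroup": ts.subgroup_of.get(pt, "none"),
            "icd_flag": int(pt in ts.icd_related),
        }
        for pt in sorted(ts.pt_names)
    ]
    pd.DataFrame(rows, columns=["pt", "hlgt", "subgroup", "icd_flag"]).to_csv(
        path, index=False
    )
    return Path(path)


def default_termset() -> TermSet:
    """The termset shipped with the package.

    Approximates the study vocabulary from terms named in the literature;
    it is not a licensed MedDRA export and can be replaced wholesale via
    :func:`load_termset`.
    """
    with resources.as_file(
        resources.files("pvpd.data").joinpath("default_termset.csv")
    ) as p:
        return load_termset(p)
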