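"""Survey dataset container shared by every pipeline stage.

A :class:`SurveyDataset` is a wide respondent x item table of ordinal
responses (e.g. 5-point Likert) together with per-respondent metadata
(group label, age, sex) and a map assigning each item to one of two item
communities — here the intrapersonal ("RRM") and social-ecological
("ARM") protective-factor domains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

META_COLUMNS = ("respondent_id", "group", "age", "sex")


@dataclass
class SurveyDataset:
    """Wide-format ordinal survey data with group labels and an item community map.

    Parameters
    ----------
    table
        DataFrame with columns ``respondent_id, group, age, sex`` followed
        by one integer column per item.
    community
        Mapping item name -> community label. Every item column must be
        mapped to exactly one community.
    categories
        Number of ordinal categories; responses must lie in ``1..categories``.
    """

    table: pd.DataFrame
    community: dict[str, str]
    categories: int = 5

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def items(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLUMNS]

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def responses(self) -> pd.DataFrame:
        """Respondent x item block of the table (ordinal codes)."""
        return self.table[self.items]

    def response_matrix(self) -> np.ndarray:
        return self.responses.to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique().tolist())

    def group_data(self, group: str) -> "SurveyDataset":
        return self.subset(self.table["group"] == group)

    def communities(self) -> list[str]:
        return sorted(set(self.community.values()))

    def items_in(self, community_label: str) -> list[str]:
        return [i for i in self.items if self.community[i] == community_label]

    # -- manipulation ----------------------------------------------------
    def subset(self, mask) -> "SurveyDataset":
        """Row subset preserving the original respondent order."""
        sub = self.table.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return replace(self, table=sub)

    def validate(self) -> None:
        missing_meta = [c for c in META_COLUMNS if c not in self.table.columns]
        if missing_meta:
            raise ValueError(f"missing metadata columns: {missing_meta}")
        items = self.items
        if not items:
            raise ValueError("dataset has no item columns")
        unmapped = [i for i in items if i not in self.community]
        if unmapped:
            raise ValueError(f"items not mapped to a community: {unmapped}")
        resp = self.table[items]
        if resp.isna().any().any():
            raise ValueError("missing responses are not allowed")
        vals = resp.to_numpy()
        if len(vals) and (vals.min() < 1 or vals.max() > self.categories):
            raise ValueError(
                f"responses must lie in 1..{self.categories}; "
                f"found range [{vals.min()}, {vals.max()}]"
            )

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, community: dict[str, str], categories: int = 5) -> "SurveyDataset":
        table = pd.read_csv(path)
        return cls(table=table, community=community, categories=categories)

    def community_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"community": self.community, "categories": self.categories}, fh, indent=2)


def default_community_map(n_items_a: int = 10, n_items_b: int = 17) -> dict[str, str]:
    """Item -> community map for the standard two-domain item set.

    ``R1..R{n_items_a}`` form the intrapersonal ("RRM") community and
    ``A1..A{n_items_b}`` the social-ecological ("ARM") community.
    """
    names = {f"R{i + 1}": "RRM" for i in range(n_items_a)}
    names.update({f"A{i + 1}": "ARM" for i in range(n_items_b)})
    return names
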