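"""Synthetic code vocabulary mapping clinical codes to analytic categories.

Real UK primary-care (Read) and hospital (ICD-10) codelists are licensed and
are not reproduced; a small synthetic vocabulary with the same category
structure ships with the package.  Categories: ``uti``, ``sepsis`` (with
source subcategories), ``recurrent_uti``, ``referral``, ``smoking_status``
(non / ex / current), ``comorbidity:<charlson_group>`` (with the classic
17-group Charlson weights), ``other_infection`` and ``none``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


@lru_cache(maxsize=1)
def load_codelist() -> pd.DataFrame:
    """Return the shipped codelist as a DataFrame.

    Columns: ``code``, ``description``, ``category``, ``subcategory``,
    ``weight`` (Charlson weight, populated only for comorbidity codes).
    """
    ref = resources.files("uti_episodes.data").joinpath("codelist.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, dtype={"code": str, "category": str})
    df["subcategory"] = df["subcategory"].fillna("")
    return df


@lru_cache(maxsize=1)
def charlson_weights() -> dict[str, int]:
    """Charlson group -> integer weight, from the shipped codelist."""
    df = load_codelist()
    rows = df[df["category"].str.startswith("comorbidity:")]
    return {
        cat.split(":", 1)[1]: int(w)
        for cat, w in zip(rows["category"], rows["weight"])
    }


def codes_for(category: str) -> list[str]:
    """All codes whose category equals (or for prefixed categories, starts
    with) ``category``."""
    df = load_codelist()
    mask = (df["category"] == category) | df["category"].str.startswith(category + ":")
    return df.loc[mask, "code"].tolist()
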