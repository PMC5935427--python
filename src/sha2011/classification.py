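"""Disease and age classification rules.

Maps ICD-10 codes to the 21 chapter labels used in the disease tables, maps
chapters to the three broad Global Burden of Disease (GBD) cause groups
(I communicable/maternal/perinatal/nutritional, II non-communicable,
III injuries), and maps integer ages to single-year bins.

Notes on the rule set
---------------------
* Codes R95-R99 (ill-defined and unknown causes of mortality) are split out
  of the symptoms chapter into a separate "Death" class, so that deaths with
  no established diagnosis can be tabulated on their own row.  The split is
  part of the rules file and can be redefined by the user.
* The GBD mapping is chapter-coarse: every ICD chapter maps to exactly one
  of the three broad groups.  Respiratory infections therefore fall in
  group II through the respiratory chapter; a cause-level mapping is out of
  scope and the rules file lets users rearrange the grouping.
* Age bins are half-open ``[lower, upper)`` integer-year intervals.  The
  default bins are the 14 single-year bins "0-1" ... "13-14".  The children
  scope is inclusive of age 14 ("aged 14 and below"), so age 14 falls in an
  explicit overflow bin ``"14"`` that is part of children totals but not a
  column of the single-year table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ClassificationError

# -- canonical vocabulary ---------------------------------------------------

UNCLASSIFIED = "unclassified"

#: chapter labels in canonical table order
CHAPTER_ORDER = [
    "Infectious diseases and parasitic diseases",
    "Tumor",
    "Blood diseases",
    "Endocrine, nutritional and metabolic disease",
    "Mental and behavior disorders",
    "Nervous system diseases",
    "Eye diseases",
    "Ear diseases",
    "Circulatory system diseases",
    "Respiratory system diseases",
    "Digestive system diseases",
    "Skin and subcutaneous tissue disease",
    "Muscular and connective tissue diseases",
    "Urogenital system diseases",
    "Pregnancy, childbirth and puerperium diseases",
    "Perinatal diseases",
    "Congenital anomalies and chromosomal abnormalities",
    "Symptoms, signs, clinical and laboratory abnormalities",
    "Injury, poisoning and external causes",
    "Death",
    "Factors influencing health status",
]

GROUP_I = "group_I_communicable_maternal_perinatal_nutritional"
GROUP_II = "group_II_noncommunicable"
GROUP_III = "group_III_injury"
GBD_GROUPS = [GROUP_I, GROUP_II, GROUP_III]

_DEFAULT_RANGES: list[tuple[str, str, str]] = [
    ("A00", "B99", "Infectious diseases and parasitic diseases"),
    ("C00", "D48", "Tumor"),
    ("D50", "D89", "Blood diseases"),
    ("E00", "E90", "Endocrine, nutritional and metabolic disease"),
    ("F00", "F99", "Mental and behavior disorders"),
    ("G00", "G99", "Nervous system diseases"),
    ("H00", "H59", "Eye diseases"),
    ("H60", "H95", "Ear diseases"),
    ("I00", "I99", "Circulatory system diseases"),
    ("J00", "J99", "Respiratory system diseases"),
    ("K00", "K93", "Digestive system diseases"),
    ("L00", "L99", "Skin and subcutaneous tissue disease"),
    ("M00", "M99", "Muscular and connective tissue diseases"),
    ("N00", "N99", "Urogenital system diseases"),
    ("O00", "O99", "Pregnancy, childbirth and puerperium diseases"),
    ("P00", "P96", "Perinatal diseases"),
    ("Q00", "Q99", "Congenital anomalies and chromosomal abnormalities"),
    ("R00", "R94", "Symptoms, signs, clinical and laboratory abnormalities"),
    ("R95", "R99", "Death"),
    ("S00", "T98", "Injury, poisoning and external causes"),
    ("V01", "Y98", "Injury, poisoning and external causes"),
    ("Z00", "Z99", "Factors influencing health status"),
]

_DEFAULT_GBD = {label: GROUP_II for label in CHAPTER_ORDER}
_DEFAULT_GBD.update(
    {
        "Infectious diseases and parasitic diseases": GROUP_I,
        "Pregnancy, childbirth and puerperium diseases": GROUP_I,
        "Perinatal diseases": GROUP_I,
        "Injury, poisoning and external causes": GROUP_III,
    }
)

_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.[0-9A-Z]{1,4})?$")

#: age-bin label for exactly 14 years (children scope, outside the 0-13 table)
AGE_OVERFLOW_BIN = "14"
#: age-bin label for everyone above the children scope (total-population cube)
AGE_ADULT_BIN = "15+"


def _code_key(code: str) -> int:
    """Order-preserving integer key for a 3-character ICD-10 prefix."""
    m = _CODE_RE.match(code.strip().upper())
    if m is None:
        raise ClassificationError(f"not a valid ICD-10 code: {code!r}")
    return (ord(m.group(1)) - ord("A")) * 100 + int(m.group(2))


@dataclass
class ClassificationRules:
    """Chapter ranges, GBD grouping and age bins used to build the cube."""

    icd_chapter_ranges: list[tuple[str, str, str]] = field(
        default_factory=lambda: list(_DEFAULT_RANGES)
    )
    gbd_group_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_GBD))
    age_bins: list[tuple[int, int, str]] = field(
        default_factory=lambda: [(a, a + 1, f"{a}-{a + 1}") for a in range(14)]
    )
    children_age_max: int = 14  # inclusive

    def __post_init__(self) -> None:
        keys = sorted(
            (_code_key(s), _code_key(e), lab) for s, e, lab in self.icd_chapter_ranges
        )
        for (s1, e1, l1), (s2, e2, l2) in zip(keys, keys[1:]):
            if e1 < s1 or s2 <= e1:
                raise ClassificationError(
                    f"chapter ranges overlap or are inverted near {l1!r}/{l2!r}"
                )
        self._range_keys = keys
        labels = {lab for _, _, lab in self.icd_chapter_ranges}
        missing = labels - set(self.gbd_group_map)
        if missing:
            raise ClassificationError(f"chapters missing from GBD map: {sorted(missing)}")
        bins = sorted(self.age_bins)
        for (lo1, hi1, _), (lo2, _, _) in zip(bins, bins[1:]):
            if hi1 > lo2:
                raise ClassificationError("age bins overlap")

    # the label set, in canonical order, restricted to labels this rule set uses
    @property
    def chapter_labels(self) -> list[str]:
        used = {lab for _, _, lab in self.icd_chapter_ranges}
        ordered = [lab for lab in CHAPTER_ORDER if lab in used]
        ordered += sorted(used - set(ordered))
        return ordered

    @property
    def child_bin_labels(self) -> list[str]:
        """All bins counting toward the children scope, incl. the overflow bin."""
        return [lab for _, _, lab in self.age_bins] + [AGE_OVERFLOW_BIN]


def default_rules() -> ClassificationRules:
    return ClassificationRules()


def load_rules(path) -> ClassificationRules:
    """Load a rules file (YAML) in the format shipped under ``data/``."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _rules_from_doc(doc)


def packaged_rules() -> ClassificationRules:
    """The versioned rules file shipped with the package."""
    text = resources.files("sha2011").joinpath("data/classification_rules.yaml").read_text()
    return _rules_from_doc(yaml.safe_load(text))


def _rules_from_doc(doc: dict) -> ClassificationRules:
    kwargs = {}
    if "icd_chapter_ranges" in doc:
        kwargs["icd_chapter_ranges"] = [
            (r["start"], r["end"], r["label"]) for r in doc["icd_chapter_ranges"]
        ]
    if "gbd_group_map" in doc:
        kwargs["gbd_group_map"] = dict(doc["gbd_group_map"])
    if "age_bins" in doc:
        kwargs["age_bins"] = [(b["lower"], b["upper"], b["label"]) for b in doc["age_bins"]]
    if "children_age_max" in doc:
        kwargs["children_age_max"] = int(doc["children_age_max"])
    return ClassificationRules(**kwargs)


# -- operations -------------------------------------------------------------


def icd10_chapter(code: str, rules: ClassificationRules | None = None) -> str:
    """Chapter label for one ICD-10 code.

    Raises :class:`ClassificationError` for syntactically invalid codes;
    returns ``"unclassified"`` for valid codes not covered by any range.
    """
    rules = rules or default_rules()
    key = _code_key(code)
    for start, end, label in rules._range_keys:
        if start <= key <= end:
            return label
    return UNCLASSIFIED


def icd10_chapter_series(codes: pd.Series, rules: ClassificationRules | None = None) -> pd.Series:
    """Vectorized chapter lookup; blank/missing codes become ``"unclassified"``."""
    rules = rules or default_rules()
    codes = codes.fillna("").astype(str).str.strip().str.upper()
    prefix_ok = codes.str.match(_CODE_RE)
    keys = np.full(len(codes), -1, dtype=int)
    ok = prefix_ok.to_numpy()
    if ok.any():
        sub = codes[prefix_ok]
        keys[ok] = (sub.str[0].map(ord) - ord("A")) * 100 + sub.str[1:3].astype(int)
    out = np.array([UNCLASSIFIED] * len(codes), dtype=object)
    for start, end, label in rules._range_keys:
        out[(keys >= start) & (keys <= end)] = label
    return pd.Series(out, index=codes.index, name="disease_class")


def gbd_group(chapter_label: str, rules: ClassificationRules | None = None) -> str:
    rules = rules or default_rules()
    try:
        return rules.gbd_group_map[chapter_label]
    except KeyError:
        raise ClassificationError(f"unknown chapter label: {chapter_label!r}") from None


def age_bin(age_years: int, rules: ClassificationRules | None = None) -> str:
    """Bin label for one integer age; errors when the age is outside all bins."""
    rules = rules or default_rules()
    for lo, hi, label in rules.age_bins:
        if lo <= age_years < hi:
            return label
    raise ClassificationError(f"age {age_years} outside all configured bins")


def age_bin_series(ages: pd.Series, rules: ClassificationRules | None = None) -> pd.Series:
    """Vectorized bin lookup over the full population.

    Ages beyond the configured bins fall in the overflow bin (exactly the
    children boundary age) or the adult bin, so the total-population cube
    keeps every record.
    """
    rules = rules or default_rules()
    ordered = sorted(rules.age_bins)
    uppers = [hi for _, hi, _ in ordered] + [rules.children_age_max + 1, 10**9]
    labels = [label for _, _, label in ordered] + [AGE_OVERFLOW_BIN, AGE_ADULT_BIN]
    idx = np.searchsorted(np.asarray(uppers), ages.to_numpy(), side="right")
    out = np.array(labels, dtype=object)[np.clip(idx, 0, len(labels) - 1)]
    return pd.Series(out, index=ages.index, name="age_bin")
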