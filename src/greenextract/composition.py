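"""Fatty-acid, sterol and tocopherol table handling.

Parses chromatography-style analyte labels ("C18:1 n-9" and typographic
variants), sums fatty-acid classes (SFA: no double bonds, MUFA: one,
PUFA: two or more), aggregates tocopherols into alpha-tocopherol
equivalents, and compares two replicate profiles analyte-by-analyte with
Welch's two-sample test computed from summary statistics.

Below-quantification-limit entries are stored as censored values carrying
their limit; they are excluded from sums and contribute zero (flagged) to
vitamin-E equivalents.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FattyAcid",
    "FattyAcidParseError",
    "Measurement",
    "FattyAcidProfile",
    "TocopherolPanel",
    "VitaminEResult",
    "ALPHA_TE_FACTORS",
    "parse_fatty_acid",
    "class_sums",
    "vitamin_e_equivalents",
    "compute_yield",
    "welch_from_summary",
    "compare_profiles",
]

#: Potency of beta/gamma/delta tocopherol relative to alpha, for vitamin-E
#: activity expressed in alpha-tocopherol equivalents.
ALPHA_TE_FACTORS = {"alpha": 1.0, "beta": 0.5, "gamma": 0.1, "delta": 0.03}


class FattyAcidParseError(ValueError):
    """Raised for fatty-acid labels that do not parse."""


@dataclass(frozen=True)
class FattyAcid:
    """A fatty acid identified by chain length, unsaturation and omega class."""

    carbons: int
    double_bonds: int = 0
    omega: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 4 or self.carbons % 2:
            raise ValueError(f"carbons must be an even integer >= 4, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")

    @property
    def lipid_class(self) -> str:
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"

    @property
    def shorthand(self) -> str:
        s = f"C{self.carbons}"
        if self.double_bonds or self.omega is not None:
            s += f":{self.double_bonds}"
        if self.omega is not None:
            s += f" n-{self.omega}"
        return s


_LABEL_RE = re.compile(
    r"^C(?P<carbons>\d+)(?::(?P<db>\d+))?(?:\s*n-(?P<omega>\d+))?$"
)


def _normalize_label(label: str) -> str:
    # unify unicode minus/dash variants and collapse whitespace around n-x
    s = label.strip()
    for dash in ("−", "–", "—"):
        s = s.replace(dash, "-")
    s = re.sub(r"\*?n\*?\s*-\s*", "n-", s)
    s = re.sub(r"\s+", " ", s)
    return s


def parse_fatty_acid(label: str) -> FattyAcid:
    """Parse a label like ``C18:1 n-9`` (typography-tolerant) into a
    :class:`FattyAcid`.  Raises :class:`FattyAcidParseError` otherwise."""
    norm = _normalize_label(label)
    m = _LABEL_RE.match(norm)
    if m is None:
        raise FattyAcidParseError(f"cannot parse fatty-acid label {label!r}")
    db = int(m.group("db")) if m.group("db") else 0
    omega = int(m.group("omega")) if m.group("omega") else None
    try:
        return FattyAcid(int(m.group("carbons")), db, omega)
    except ValueError as exc:
        raise FattyAcidParseError(f"invalid fatty acid {label!r}: {exc}") from exc


@dataclass(frozen=True)
class Measurement:
    """A summary value: mean ± sd over n replicates, possibly censored.

    Censored (below-quantification-limit) entries carry the limit in
    ``mean`` and set ``below_limit``; they are excluded from aggregation.
    """

    mean: float
    sd: float | None = None
    n: int | None = None
    below_limit: bool = False

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"mean must be >= 0, got {self.mean}")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class FattyAcidProfile:
    """Named fatty-acid percentages with replicate metadata."""

    entries: dict[str, Measurement]
    yield_g_per_100g: Measurement | None = None
    name: str = ""

    def __post_init__(self) -> None:
        total = sum(m.mean for m in self.entries.values() if not m.below_limit)
        # published tables drift past 100% through per-row rounding; tolerate
        # that but reject anything that cannot be rounding alone
        if total > 102.0:
            raise ValueError(f"fatty-acid means sum to {total:.2f} > 102%")
        if total > 100.5:
            warnings.warn(
                f"fatty-acid means sum to {total:.2f}%, above 100.5%",
                stacklevel=3,
            )

    def parsed(self) -> dict[str, FattyAcid]:
        return {label: parse_fatty_acid(label) for label in self.entries}


def class_sums(profile: FattyAcidProfile) -> dict[str, float]:
    """Sum of mean percentages per lipid class: {'SFA', 'MUFA', 'PUFA'}."""
    out = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for label, meas in profile.entries.items():
        if meas.below_limit:
            continue
        out[parse_fatty_acid(label).lipid_class] += meas.mean
    return out


@dataclass
class TocopherolPanel:
    """Tocopherol contents in mg/kg fat, plus (censored) tocotrienols."""

    alpha: Measurement
    beta: Measurement
    gamma: Measurement
    delta: Measurement
    tocotrienols: dict[str, Measurement] = field(default_factory=dict)
    name: str = ""


@dataclass(frozen=True)
class VitaminEResult:
    """Alpha-tocopherol-equivalent activity with censoring flags."""

    te_per_100g: float
    censored_excluded: tuple[str, ...] = ()


def vitamin_e_equivalents(panel: TocopherolPanel) -> VitaminEResult:
    """Vitamin-E activity in alpha-tocopherol equivalents per 100 g fat.

    (1.0·alpha + 0.5·beta + 0.1·gamma + 0.03·delta) / 10 with contents in
    mg/kg fat.  Below-limit isomers contribute zero and are flagged.
    """
    total = 0.0
    excluded: list[str] = []
    for isomer, factor in ALPHA_TE_FACTORS.items():
        meas: Measurement = getattr(panel, isomer)
        if meas.below_limit:
            excluded.append(isomer)
            continue
        total += factor * meas.mean
    return VitaminEResult(te_per_100g=total / 10.0, censored_excluded=tuple(excluded))


def compute_yield(extract_mass_g: float, dry_seed_mass_g: float) -> float:
    """Extraction yield in percent: 100 × extract mass / dry seed mass."""
    if dry_seed_mass_g <= 0:
        raise ValueError("dry seed mass must be > 0")
    if extract_mass_g < 0:
        raise ValueError("extract mass must be >= 0")
    return 100.0 * extract_mass_g / dry_seed_mass_g


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's two-sample t statistic from summary statistics.

    Returns (t, degrees of freedom, two-sided p).  With both sds zero the
    test degenerates: p is 1.0 for equal means, 0.0 otherwise.
    """
    if min(n1, n2) < 2:
        raise ValueError("Welch test needs n >= 2 in both groups")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0.0:
        return (0.0, float(n1 + n2 - 2), 1.0) if mean1 == mean2 else (np.inf, 1.0, 0.0)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compare_profiles(
    a: FattyAcidProfile, b: FattyAcidProfile, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-analyte equivalence table between two profiles.

    Analytes present in only one profile are reported as incomparable.
    Returns a frame with a ``significant`` flag at the requested level and
    carries the count of significant differences in ``frame.attrs``.
    """
    rows = []
    for label in sorted(set(a.entries) | set(b.entries)):
        ma, mb = a.entries.get(label), b.entries.get(label)
        if ma is None or mb is None:
            rows.append(
                {
                    "analyte": label,
                    "comparable": False,
                    "t": np.nan,
                    "df": np.nan,
                    "p": np.nan,
                    "significant": False,
                }
            )
            continue
        if ma.n is None or mb.n is None or min(ma.n, mb.n) < 2:
            raise ValueError(f"analyte {label!r} lacks replicate counts (n >= 2)")
        t, df, p = welch_from_summary(ma.mean, ma.sd or 0.0, ma.n, mb.mean, mb.sd or 0.0, mb.n)
        rows.append(
            {
                "analyte": label,
                "comparable": True,
                "mean_a": ma.mean,
                "mean_b": mb.mean,
                "t": t,
                "df": df,
                "p": p,
                "significant": bool(p < alpha),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n_significant"] = int(frame["significant"].sum())
    return frame
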