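"""Chemical-genetic screen scoring and profile set overlaps.

A genome-wide deletion collection is pinned on agar with and without a
sub-inhibitory drug dose; each strain's colony sizes (quadruplicate spots)
are reduced if the deleted gene buffers the drug's target pathway.  Scoring:

1. normalize every colony size by the median size on its plate,
2. average replicates per strain and condition,
3. ratio r = drug / control,
4. robust z = (median(r) - r) / (1.4826 * MAD(r)), so a growth deficit
   gives a positive z; strains with z >= threshold are called sensitive.

Profile comparisons report Venn counts, conditional overlap percentages and
exact hypergeometric enrichment p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePopulationError

COLONY_COLUMNS = ["strain", "plate", "replicate", "size"]


@dataclass
class ColonyTable:
    """Colony sizes for one condition: strain, plate, replicate, size."""

    rows: pd.DataFrame
    condition_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLONY_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"colony table missing columns: {missing}")
        if (self.rows["size"] < 0).any():
            raise ValueError("colony sizes must be non-negative")
        self.rows = self.rows[COLONY_COLUMNS].reset_index(drop=True)

    @property
    def strains(self) -> set[str]:
        return set(self.rows["strain"])


def read_colony_table(path: str | Path, condition_label: str | None = None) -> ColonyTable:
    df = pd.read_csv(path, sep="\t")
    return ColonyTable(df, condition_label or Path(path).stem)


def write_colony_table(table: ColonyTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def _strain_means(table: ColonyTable) -> pd.Series:
    """Plate-median-normalized, replicate-averaged size per strain."""
    rows = table.rows.copy()
    plate_median = rows.groupby("plate")["size"].transform("median")
    if (plate_median <= 0).any():
        bad = sorted(rows.loc[plate_median <= 0, "plate"].unique())
        raise DegeneratePopulationError(f"plates with non-positive median size: {bad}")
    rows["norm"] = rows["size"] / plate_median
    return rows.groupby("strain")["norm"].mean()


def compute_zscores(
    drug: ColonyTable, control: ColonyTable, threshold: float = 1.88
) -> pd.DataFrame:
    """Robust sensitivity z-scores per strain (columns strain, ratio, z, sensitive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    drug_mean = _strain_means(drug)
    ctrl_mean = _strain_means(control)
    common = drug_mean.index.intersection(ctrl_mean.index)
    if common.empty:
        raise ValueError("no strains shared between drug and control tables")
    missing = sorted(set(drug_mean.index) - set(common))
    if missing:
        warnings.warn(
            f"{len(missing)} strains absent from the control plate were dropped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    zero_ctrl = ctrl_mean.loc[common] <= 0
    if zero_ctrl.any():
        warnings.warn(
            f"{int(zero_ctrl.sum())} strains with zero control growth were dropped",
            stacklevel=2,
        )
        common = common[~zero_ctrl.to_numpy()]
    r = (drug_mean.loc[common] / ctrl_mean.loc[common]).to_numpy(float)
    med = float(np.median(r))
    mad = float(np.median(np.abs(r - med)))
    if mad == 0:
        if np.allclose(r, med):
            warnings.warn("all ratios identical; z-scores set to 0", stacklevel=2)
            z = np.zeros_like(r)
        else:
            raise DegeneratePopulationError(
                "MAD of drug/control ratios is zero but ratios differ; "
                "z-scores are undefined"
            )
    else:
        z = (med - r) / (1.4826 * mad)
    out = pd.DataFrame(
        {"strain": common, "ratio": r, "z": z, "sensitive": z >= threshold}
    ).reset_index(drop=True)
    return out


@dataclass
class VennStats:
    """Pairwise overlap accounting between two strain sets."""

    n_a: int
    n_b: int
    n_intersect: int
    pct_a_in_b: float
    pct_b_in_a: float
    universe_size: int | None = None
    p_hypergeom: float | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def overlap_stats(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str] | None = None
) -> VennStats:
    """Venn counts, conditional percentages and exact hypergeometric enrichment p.

    ``pct_a_in_b`` is the percentage of A that is also in B (and vice versa).
    The p-value (requires a universe) is the upper tail P(X >= |A∩B|) of a
    hypergeometric draw of |B| from the universe with |A| marked.
    """
    a, b = set(set_a), set(set_b)
    inter = a & b
    p = None
    uni_size = None
    if universe is not None:
        uni = set(universe)
        stray = (a | b) - uni
        if stray:
            raise ValueError(f"sets contain strains outside the universe: {sorted(stray)[:5]}")
        uni_size = len(uni)
        p = float(stats.hypergeom.sf(len(inter) - 1, uni_size, len(a), len(b)))
    if a:
        pct_a_in_b = 100.0 * len(inter) / len(a)
    else:
        warnings.warn("set A is empty; pct_a_in_b undefined", stacklevel=2)
        pct_a_in_b = float("nan")
    if b:
        pct_b_in_a = 100.0 * len(inter) / len(b)
    else:
        warnings.warn("set B is empty; pct_b_in_a undefined", stacklevel=2)
        pct_b_in_a = float("nan")
    return VennStats(len(a), len(b), len(inter), pct_a_in_b, pct_b_in_a, uni_size, p)


def multi_set_report(named_sets: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]]) -> pd.DataFrame:
    """Exclusive Venn-region counts for two or more named sets.

    Returns one row per non-empty membership pattern plus empty patterns with
    count 0; the region counts partition the union.
    """
    if not isinstance(named_sets, Mapping):
        names = [n for n, _ in named_sets]
        if len(names) != len(set(names)):
            raise ValueError("duplicate set names")
        named_sets = dict(named_sets)
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    sets = {n: set(v) for n, v in named_sets.items()}
    union = set().union(*sets.values())
    counts: dict[tuple[bool, ...], int] = {
        pattern: 0
        for pattern in itertools.product([True, False], repeat=len(names))
        if any(pattern)
    }
    for item in union:
        pattern = tuple(item in sets[n] for n in names)
        counts[pattern] += 1
    rows = []
    for pattern, count in sorted(counts.items(), key=lambda kv: (-sum(kv[0]), kv[0])):
        rows.append(
            {"region": "&".join(n for n, m in zip(names, pattern) if m)
             + ("" if all(pattern) else " only" if sum(pattern) == 1 else ""),
             **{f"in_{n}": m for n, m in zip(names, pattern)},
             "count": count}
        )
    df = pd.DataFrame(rows)
    df.attrs["union_size"] = len(union)
    return df
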