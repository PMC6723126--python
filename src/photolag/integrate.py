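"""Combining transcript and protein regulation calls.

Matches regulated mRNA/protein pairs by gene id, partitions features into
the four regulatory categories (regulated in both layers; protein-only;
mRNA-only with protein quantitation; mRNA-only without protein data),
computes the lag correlation grid — Pearson correlation between transcript
log2 fold-change at time i and protein log2 fold-change at time j over all
regulated pairs — and reads the transcription-to-translation delay off the
cell maximizing r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CategoryPartition:
    """Four-way regulatory accounting over both omics layers.

    Identities (validated): pairs + mRNA-only-with-data + mRNA-only-no-data
    = regulated mRNAs, and pairs + protein-only = regulated proteins.
    """

    n_genome: int
    n_mrna_evaluated: int
    n_protein_evaluated: int
    n_mrna_regulated: int
    n_protein_regulated: int
    n_pairs: int
    n_protein_only: int
    n_mrna_only_with_protein_data: int
    n_mrna_only_no_protein_data: int

    def validate(self) -> "CategoryPartition":
        counts = self.__dict__
        if any(v < 0 for v in counts.values()):
            raise ValueError("all counts must be >= 0")
        if (
            self.n_pairs
            + self.n_mrna_only_with_protein_data
            + self.n_mrna_only_no_protein_data
            != self.n_mrna_regulated
        ):
            raise ValueError("mRNA category counts do not sum to regulated mRNAs")
        if self.n_pairs + self.n_protein_only != self.n_protein_regulated:
            raise ValueError("protein category counts do not sum to regulated proteins")
        if self.n_mrna_regulated > self.n_mrna_evaluated:
            raise ValueError("more regulated than evaluated mRNAs")
        if self.n_protein_regulated > self.n_protein_evaluated:
            raise ValueError("more regulated than evaluated proteins")
        return self

    @classmethod
    def from_counts(
        cls,
        n_genome: int,
        n_mrna_evaluated: int,
        n_protein_evaluated: int,
        n_mrna_regulated: int,
        n_protein_regulated: int,
        n_pairs: int,
        n_mrna_only_no_protein_data: int,
    ) -> "CategoryPartition":
        """Complete the partition from the counts usually reported in print."""
        return cls(
            n_genome=n_genome,
            n_mrna_evaluated=n_mrna_evaluated,
            n_protein_evaluated=n_protein_evaluated,
            n_mrna_regulated=n_mrna_regulated,
            n_protein_regulated=n_protein_regulated,
            n_pairs=n_pairs,
            n_protein_only=n_protein_regulated - n_pairs,
            n_mrna_only_with_protein_data=(
                n_mrna_regulated - n_pairs - n_mrna_only_no_protein_data
            ),
            n_mrna_only_no_protein_data=n_mrna_only_no_protein_data,
        ).validate()

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _regulated_set(calls: pd.DataFrame) -> set[str]:
    if calls["feature_id"].duplicated().any():
        raise ValueError("duplicate feature ids in calls table")
    return set(calls.loc[calls["regulated"], "feature_id"])


def match_pairs(
    transcript_calls: pd.DataFrame,
    protein_calls: pd.DataFrame,
    protein_universe,
) -> pd.DataFrame:
    """Features regulated on both layers, plus protein-data flags.

    Returns one row per regulated transcript: whether any protein
    quantitation exists (membership in ``protein_universe``) and whether the
    protein is itself regulated (``is_pair``).
    """
    universe = set(protein_universe)
    t_reg = _regulated_set(transcript_calls)
    p_reg = _regulated_set(protein_calls)
    if not p_reg <= universe:
        raise ValueError("regulated proteins outside the protein universe")
    rows = [
        {
            "feature_id": f,
            "has_protein_data": f in universe,
            "is_pair": f in p_reg,
        }
        for f in sorted(t_reg)
    ]
    return pd.DataFrame(rows, columns=["feature_id", "has_protein_data", "is_pair"])


def partition_categories(
    transcript_calls: pd.DataFrame,
    protein_calls: pd.DataFrame,
    protein_universe,
    n_genome: int,
) -> CategoryPartition:
    """Build the four-way category partition from per-layer calls."""
    universe = set(protein_universe)
    t_all = set(transcript_calls["feature_id"])
    t_reg = _regulated_set(transcript_calls)
    p_reg = _regulated_set(protein_calls)
    if not p_reg <= universe:
        raise ValueError("regulated proteins outside the protein universe")
    if n_genome < len(t_all):
        raise ValueError("genome size smaller than evaluated transcript count")
    pairs = t_reg & p_reg
    t_only = t_reg - p_reg
    return CategoryPartition(
        n_genome=n_genome,
        n_mrna_evaluated=len(t_all),
        n_protein_evaluated=len(universe),
        n_mrna_regulated=len(t_reg),
        n_protein_regulated=len(p_reg),
        n_pairs=len(pairs),
        n_protein_only=len(p_reg - t_reg),
        n_mrna_only_with_protein_data=len(t_only & universe),
        n_mrna_only_no_protein_data=len(t_only - universe),
    ).validate()


@dataclass
class LagCorrelationGrid:
    """Pearson r (and r^2) between transcript log2fc at time i and protein
    log2fc at time j, over the matched regulated pairs."""

    r: pd.DataFrame                  # transcript conditions x protein conditions
    r2: pd.DataFrame
    n: int
    transcript_minutes: dict[str, float]
    protein_minutes: dict[str, float]

    def write_tsv(self, path) -> None:
        out = self.r.copy()
        out.index.name = "transcript_condition"
        combined = pd.concat({"r": self.r, "r2": self.r2}, axis=1)
        combined.index.name = "transcript_condition"
        combined.to_csv(path, sep="\t")


def _profile_matrix(profiles: pd.DataFrame, features) -> tuple[pd.DataFrame, dict]:
    sub = profiles.loc[
        profiles["feature_id"].isin(features) & profiles["minutes"].notna()
    ]
    wide = sub.pivot(index="feature_id", columns="condition", values="log2fc")
    minutes = dict(
        sub.drop_duplicates("condition").set_index("condition")["minutes"]
    )
    cond_order = sorted(minutes, key=minutes.get)
    return wide[cond_order].loc[sorted(features)], minutes


def lag_correlation(
    pairs,
    transcript_profiles: pd.DataFrame,
    protein_profiles: pd.DataFrame,
) -> LagCorrelationGrid:
    """Correlation grid over all (transcript time, protein time) cells.

    ``pairs`` is an iterable of feature ids (or a ``match_pairs`` table, in
    which case its ``is_pair`` rows are used).  Cells where either profile
    vector is constant are undefined and reported as NaN.
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = pairs.loc[pairs["is_pair"], "feature_id"]
    features = sorted(set(pairs))
    if len(features) < 3:
        raise ValueError("need >= 3 pairs for a stable correlation grid")
    T, t_min = _profile_matrix(transcript_profiles, features)
    P, p_min = _profile_matrix(protein_profiles, features)
    if T.isna().any().any() or P.isna().any().any():
        raise ValueError("pairs must have complete log2fc profiles on both layers")

    Tc = T.to_numpy() - T.to_numpy().mean(axis=0)
    Pc = P.to_numpy() - P.to_numpy().mean(axis=0)
    t_sd = np.sqrt((Tc**2).sum(axis=0))
    p_sd = np.sqrt((Pc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Tc.T @ Pc) / np.outer(t_sd, p_sd)
    r[:, p_sd == 0] = np.nan
    r[t_sd == 0, :] = np.nan
    r = np.clip(r, -1.0, 1.0)
    r_df = pd.DataFrame(r, index=T.columns, columns=P.columns)
    return LagCorrelationGrid(
        r=r_df, r2=r_df**2, n=len(features),
        transcript_minutes=t_min, protein_minutes=p_min,
    )


@dataclass
class PeakLag:
    lag_minutes: float
    transcript_condition: str
    protein_condition: str
    r: float
    r2: float
    per_row_best: pd.DataFrame


def estimate_peak_lag(grid: LagCorrelationGrid) -> PeakLag:
    """Delay maximizing r^2 over the grid; ties resolved to the smallest lag,
    then to the earliest transcript time.  Also reports each transcript
    time's best-correlated protein time."""
    cells = []
    for tc in grid.r2.index:
        for pc in grid.r2.columns:
            v = grid.r2.loc[tc, pc]
            if np.isnan(v):
                continue
            lag = grid.protein_minutes[pc] - grid.transcript_minutes[tc]
            cells.append((tc, pc, float(v), lag))
    if not cells:
        raise ValueError("all grid cells are undefined")
    best_r2 = max(c[2] for c in cells)
    contenders = [c for c in cells if abs(c[2] - best_r2) <= 1e-12]
    tc, pc, v, lag = min(
        contenders, key=lambda c: (c[3], grid.transcript_minutes[c[0]])
    )
    rows = []
    for tci in grid.r2.index:
        row = grid.r2.loc[tci].dropna()
        if row.empty:
            continue
        row_cells = [
            (pcj, float(row[pcj]),
             grid.protein_minutes[pcj] - grid.transcript_minutes[tci])
            for pcj in row.index
        ]
        row_best = max(row.to_numpy())
        pcj, r2j, lagj = min(
            (c for c in row_cells if abs(c[1] - row_best) <= 1e-12),
            key=lambda c: c[2],
        )
        rows.append({
            "transcript_condition": tci, "best_protein_condition": pcj,
            "r2": r2j, "lag_minutes": lagj,
        })
    return PeakLag(
        lag_minutes=lag,
        transcript_condition=tc,
        protein_condition=pc,
        r=float(grid.r.loc[tc, pc]),
        r2=v,
        per_row_best=pd.DataFrame(rows),
    )


def paired_profile_export(
    pairs,
    transcript_profiles: pd.DataFrame,
    protein_profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format (feature, layer, condition, minutes, log2fc) table for
    dual-axis mRNA/protein plots, deterministically ordered."""
    if isinstance(pairs, pd.DataFrame):
        pairs = pairs.loc[pairs["is_pair"], "feature_id"]
    features = sorted(set(pairs))
    frames = []
    for layer, profiles in (("transcript", transcript_profiles),
                            ("protein", protein_profiles)):
        sub = profiles.loc[
            profiles["feature_id"].isin(features) & profiles["minutes"].notna(),
            ["feature_id", "condition", "minutes", "log2fc"],
        ].copy()
        sub.insert(1, "layer", layer)
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["feature_id", "layer", "minutes"], kind="mergesort"
    ).reset_index(drop=True)
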