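"""Feature-by-sample abundance matrices with per-sample annotations.

The container is a thin wrapper around two :class:`pandas.DataFrame` objects:
``values`` (features x samples, nonnegative) and ``samples`` (one row per
sample: condition, replicate, batch, minutes-after-pulse, is_control).
Missing measurements (``NaN``) are permitted only in the protein layer,
where they record that a protein was not quantified in a replicate run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import PulseDesign

LAYERS = ("transcript", "protein")

SAMPLE_COLUMNS = ["condition", "replicate", "batch", "minutes", "is_control"]


def sample_table(design: PulseDesign, layer: str) -> pd.DataFrame:
    """Build the sample annotation table implied by a :class:`PulseDesign`.

    Each replicate experiment is one batch (one sequencing/labelling run
    containing every condition), named ``R1 .. Rn``.
    """
    minutes = design.condition_minutes(layer)
    rows = []
    for cond in design.conditions_for(layer):
        is_control = cond == design.control_label
        for r in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample": f"{cond}_R{r}",
                    "condition": cond,
                    "replicate": r,
                    "batch": f"R{r}",
                    "minutes": np.nan if is_control else minutes[cond],
                    "is_control": is_control,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class AbundanceMatrix:
    """Nonnegative feature-by-sample measurements for one omics layer."""

    values: pd.DataFrame
    samples: pd.DataFrame
    layer: str
    transformed: bool = False  # glog-scale matrices may hold negative values

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if not self.values.columns.equals(self.samples.index):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(f"sample annotation mismatch: {sorted(missing)}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples table lacks column {col!r}")
        vals = self.values.to_numpy(dtype=float)
        if not self.transformed and np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be nonnegative")
        if self.layer == "transcript" and np.isnan(vals).any():
            raise ValueError("transcript layer must not contain missing values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    # -- convenience --------------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def control_label(self) -> str:
        ctrl = self.samples.loc[self.samples["is_control"], "condition"].unique()
        if len(ctrl) != 1:
            raise ValueError("expected exactly one control condition")
        return str(ctrl[0])

    def condition_columns(self, condition: str) -> list[str]:
        cols = self.samples.index[self.samples["condition"] == condition]
        if len(cols) == 0:
            raise KeyError(f"condition {condition!r} has no samples")
        return list(cols)

    def condition_minutes(self) -> dict[str, float]:
        sub = self.samples.loc[~self.samples["is_control"]]
        return dict(
            sub.drop_duplicates("condition").set_index("condition")["minutes"]
        )

    def with_values(
        self, values: pd.DataFrame, transformed: bool | None = None
    ) -> "AbundanceMatrix":
        return AbundanceMatrix(
            values=values,
            samples=self.samples.copy(),
            layer=self.layer,
            transformed=self.transformed if transformed is None else transformed,
        )

    # -- IO -----------------------------------------------------------------

    def write_tsv(self, values_path: str | Path, samples_path: str | Path | None = None) -> None:
        """Write the matrix (missing values as empty fields) and, optionally,
        the sample annotation sidecar."""
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(values_path, sep="\t", na_rep="")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t")

    @classmethod
    def read_tsv(
        cls,
        values_path: str | Path,
        layer: str,
        samples_path: str | Path | None = None,
        design: PulseDesign | None = None,
    ) -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        values.columns = pd.Index([str(c) for c in values.columns], name="sample")
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col=0)
            samples["is_control"] = samples["is_control"].astype(bool)
        elif design is not None:
            samples = sample_table(design, layer).loc[list(values.columns)]
        else:
            raise ValueError("provide either samples_path or design")
        return cls(values=values, samples=samples, layer=layer)
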