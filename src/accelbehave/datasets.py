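"""The eight factorial training datasets and the train/test split.

From one labelled, extended, 40 Hz feature frame the full factorial of
(variables: base | extended) x (frequency: 40 | 1 Hz) x (duration policy:
inconsistent | standardised) is derived.  Standardisation caps each
behaviour's contribution at 60 s — 2400 records at 40 Hz, 60 at 1 Hz — by
uniform random subsampling; behaviours at or under the cap are kept whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BASE_VARIABLES, EXTENDED_VARIABLES, FeatureFrame, to_1hz
from .synthetic import BEHAVIOURS

log = logging.getLogger(__name__)

VARIANT_FACTORS: tuple[tuple[str, int, str], ...] = tuple(
    (variables, frequency, policy)
    for variables in ("base", "extended")
    for frequency in (40, 1)
    for policy in ("inconsistent", "standardised"))


def variant_id(variables: str, frequency: int, policy: str) -> str:
    return f"{variables}_{policy}_{frequency}hz"


@dataclass
class DatasetVariant:
    """One cell of the factorial: labelled records plus provenance."""

    variables: str          # "base" | "extended"
    frequency: int          # 40 | 1 (Hz)
    duration_policy: str    # "standardised" | "inconsistent"
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def id(self) -> str:
        return variant_id(self.variables, self.frequency, self.duration_policy)

    @property
    def variable_columns(self) -> tuple[str, ...]:
        return BASE_VARIABLES if self.variables == "base" else EXTENDED_VARIABLES

    def per_behaviour_counts(self) -> dict[str, int]:
        return self.records["behaviour"].value_counts().to_dict()

    def manifest(self) -> dict:
        return {"id": self.id, "variables": self.variables,
                "frequency_hz": self.frequency,
                "duration_policy": self.duration_policy,
                "n_records": len(self.records),
                "per_behaviour": self.per_behaviour_counts(),
                **self.provenance}


def standardise_durations(records: pd.DataFrame, cap_s: float = 60.0,
                          frequency: int = 40, seed: int = 0) -> pd.DataFrame:
    """Cap each behaviour at ``cap_s * frequency`` records by random subsampling.

    Behaviours over the cap lose a uniform random subset (without
    replacement); behaviours at or under it are retained in full.  Record
    contents are never altered, only dropped.
    """
    if cap_s <= 0:
        raise ValueError("cap_s must be positive")
    cap = round(cap_s * frequency)
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for b, idx in records.groupby("behaviour", sort=True).indices.items():
        if len(idx) > cap:
            sel = np.sort(rng.choice(idx, size=cap, replace=False))
            log.info("standardise: %s %d -> %d records", b, len(idx), cap)
        else:
            sel = np.sort(idx)
            log.info("standardise: %s %d records kept whole (cap %d)",
                     b, len(idx), cap)
        keep.append(sel)
    order = np.sort(np.concatenate(keep))
    return records.iloc[order].reset_index(drop=True)


def derive_all_variants(frame40: FeatureFrame, seed: int = 0,
                        cap_s: float = 60.0) -> dict[str, DatasetVariant]:
    """Derive the eight factorial variants from an extended 40 Hz frame.

    1 Hz variants are averaged first, then standardised, so the cap applies
    in each variant's own time base.  Base variants are column subsets of the
    extended ones.  Deterministic for a fixed seed.
    """
    if frame40.variant != "extended":
        raise ValueError("source frame must carry the extended variable set")
    if round(frame40.frequency_hz) != 40:
        raise ValueError("source frame must be at 40 Hz")
    if "behaviour" not in frame40.data.columns:
        raise ValueError("source frame must be labelled")
    present = set(frame40.data["behaviour"].unique())
    missing = [b for b in BEHAVIOURS if b not in present]
    if missing:
        log.warning("behaviours absent from source frame: %s", missing)

    frames = {40: frame40, 1: to_1hz(frame40)}
    seeds = np.random.SeedSequence(seed).generate_state(4)
    out: dict[str, DatasetVariant] = {}
    for i, frequency in enumerate((40, 1)):
        ext = frames[frequency]
        for j, policy in enumerate(("inconsistent", "standardised")):
            sub_seed = int(seeds[2 * i + j])
            records = ext.data
            if policy == "standardised":
                records = standardise_durations(records, cap_s, frequency, sub_seed)
            for variables in ("base", "extended"):
                cols = [c for c in records.columns
                        if c in ("time_s", "individual_id", "bout_id", "behaviour")
                        or c in (BASE_VARIABLES if variables == "base"
                                 else EXTENDED_VARIABLES)]
                v = DatasetVariant(variables, frequency, policy,
                                   records[cols].reset_index(drop=True),
                                   provenance={"seed": seed, "subsample_seed": sub_seed,
                                               "cap_s": cap_s})
                out[v.id] = v
    assert len(out) == 8
    return out


def split_train_test(records: pd.DataFrame | DatasetVariant,
                     train_fraction: float = 0.6, seed: int = 0,
                     by_bout: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random record-level partition into train and test.

    ``by_bout=True`` partitions whole bouts instead (a stricter split for
    sensitivity analysis of autocorrelation leakage); the fraction then
    applies to bout counts.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    df = records.records if isinstance(records, DatasetVariant) else records
    rng = np.random.default_rng(seed)
    if by_bout:
        if "bout_id" not in df.columns:
            raise ValueError("by_bout split needs a bout_id column")
        bouts = df["bout_id"].unique()
        n_train = round(len(bouts) * train_fraction)
        train_bouts = set(rng.choice(bouts, size=n_train, replace=False).tolist())
        mask = df["bout_id"].isin(train_bouts).to_numpy()
    else:
        n_train = round(len(df) * train_fraction)
        idx = rng.permutation(len(df))[:n_train]
        mask = np.zeros(len(df), dtype=bool)
        mask[idx] = True
    train = df[mask].reset_index(drop=True)
    test = df[~mask].reset_index(drop=True)
    lost = set(df["behaviour"].unique()) - set(train["behaviour"].unique())
    if lost:
        log.warning("behaviours absent from training split: %s", sorted(lost))
    return train, test
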