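"""Time-profile engine: per-gene averages over flow timepoints, origin and
slope by ordinary least squares, and band-based similarity / divergence
search against a reference profile.

A similarity value ``s`` in [0, 2] defines a band ``[ref - s, ref + s]``
around the reference at every timepoint; *similar* profiles lie inside the
band at every timepoint (inclusive), *divergent* profiles lie outside it at
every timepoint (the symmetric convention; an any-timepoint alternative is
available behind a flag).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, validate_samples


@dataclass
class ProfileSet:
    """Per-gene per-timepoint averages (genes x ascending timepoints)."""

    averages: pd.DataFrame

    def __post_init__(self) -> None:
        cols = [float(c) for c in self.averages.columns]
        if cols != sorted(cols):
            raise ValueError("profile timepoints must be ascending")
        self.averages.columns = cols

    @property
    def timepoints_h(self) -> list[float]:
        return list(self.averages.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.averages.index


@dataclass
class SimilarityQuery:
    """A reference profile, a band half-width ``s`` in [0, 2], and a mode."""

    reference: pd.Series  # timepoint -> value
    s: float
    mode: str = "similar"

    def __post_init__(self) -> None:
        if not 0 <= self.s <= 2:
            raise ValueError(f"similarity value s must be in [0, 2], got {self.s}")
        if self.mode not in ("similar", "divergent"):
            raise ValueError(f"mode must be 'similar' or 'divergent', got {self.mode!r}")


def build_profiles(m: ExpressionMatrix, samples: pd.DataFrame) -> ProfileSet:
    """Average expression per gene and timepoint over all available samples.

    Static samples count as t = 0; samples without a timepoint are ignored.
    A timepoint that ends up with zero samples is dropped with a warning,
    never imputed.
    """
    samples = validate_samples(samples, m)
    tp = samples["timepoint_h"].to_numpy(dtype=float).copy()
    tp[(samples["environment"] == "static").to_numpy() & np.isnan(tp)] = 0.0
    keep = ~np.isnan(tp)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} samples without a timepoint were excluded", stacklevel=2)
    if not keep.any():
        raise ValueError("no samples carry a timepoint")
    X = m.values.to_numpy(dtype=float)[:, keep]
    tp = tp[keep]
    cols = {}
    for t in sorted(set(tp)):
        cols[float(t)] = X[:, tp == t].mean(axis=1)
    return ProfileSet(pd.DataFrame(cols, index=m.gene_ids))


def profile_regression(profiles: ProfileSet) -> pd.DataFrame:
    """Ordinary least squares of averages on hours: intercept (origin) at
    t = 0 and slope per hour, for every gene at once."""
    t = np.asarray(profiles.timepoints_h, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("profile regression needs >= 2 distinct timepoints")
    Y = profiles.averages.to_numpy(dtype=float)
    t_bar = t.mean()
    denom = ((t - t_bar) ** 2).sum()
    slope = (Y - Y.mean(axis=1, keepdims=True)) @ (t - t_bar) / denom
    origin = Y.mean(axis=1) - slope * t_bar
    return pd.DataFrame({"origin": origin, "slope": slope}, index=profiles.gene_ids)


def _check_query(profiles: ProfileSet, q: SimilarityQuery) -> np.ndarray:
    ref = q.reference
    if isinstance(ref, pd.Series):
        ref_t = [float(i) for i in ref.index]
        if ref_t != profiles.timepoints_h:
            raise ValueError(
                f"query timepoints {ref_t} do not match profile timepoints "
                f"{profiles.timepoints_h}"
            )
        return ref.to_numpy(dtype=float)
    ref = np.asarray(ref, dtype=float)
    if len(ref) != len(profiles.timepoints_h):
        raise ValueError("reference length does not match the profile timepoints")
    return ref


def mean_reference(profiles: ProfileSet, genes) -> pd.Series:
    """Unweighted mean profile of a gene selection, usable as a reference."""
    genes = pd.Index(genes)
    missing = genes.difference(profiles.gene_ids)
    if len(missing):
        raise ValueError(f"genes absent from profiles: {missing[:5].tolist()}")
    return profiles.averages.loc[genes].mean(axis=0)


def similarity_search(profiles: ProfileSet, q: SimilarityQuery) -> list:
    """Genes whose profile lies within [ref - s, ref + s] at every timepoint."""
    if q.mode != "similar":
        raise ValueError("similarity_search requires a query with mode='similar'")
    ref = _check_query(profiles, q)
    Y = profiles.averages.to_numpy(dtype=float)
    inside = np.abs(Y - ref[None, :]) <= q.s
    return profiles.gene_ids[inside.all(axis=1)].tolist()


def divergence_search(
    profiles: ProfileSet, q: SimilarityQuery, any_timepoint: bool = False
) -> list:
    """Genes whose profile lies strictly outside the band.

    Default: outside at *every* timepoint (symmetric with similarity);
    ``any_timepoint=True`` relaxes this to at least one timepoint outside.
    """
    if q.mode != "divergent":
        raise ValueError("divergence_search requires a query with mode='divergent'")
    ref = _check_query(profiles, q)
    Y = profiles.averages.to_numpy(dtype=float)
    outside = np.abs(Y - ref[None, :]) > q.s
    hit = outside.any(axis=1) if any_timepoint else outside.all(axis=1)
    return profiles.gene_ids[hit].tolist()


def export_profile_table(profiles: ProfileSet) -> pd.DataFrame:
    """One row per gene: per-timepoint averages plus origin and slope."""
    if len(profiles.gene_ids) == 0:
        raise ValueError("profiles are empty")
    reg = profile_regression(profiles)
    out = profiles.averages.copy()
    out.columns = [f"avg_{c:g}h" for c in out.columns]
    out["origin"] = reg["origin"]
    out["slope"] = reg["slope"]
    out.index.name = "gene_id"
    return out


def write_profile_table(profiles: ProfileSet, tsv_path=None, json_path=None) -> pd.DataFrame:
    table = export_profile_table(profiles)
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", float_format="%.17g")
    if json_path is not None:
        payload = {
            "timepoints_h": profiles.timepoints_h,
            "genes": {
                g: {
                    "averages": profiles.averages.loc[g].tolist(),
                    "origin": float(table.loc[g, "origin"]),
                    "slope": float(table.loc[g, "slope"]),
                }
                for g in table.index
            },
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return table


def read_profile_table(tsv_path) -> ProfileSet:
    """Re-parse an exported profile table (round-trips bit-exactly)."""
    table = pd.read_csv(tsv_path, sep="\t", index_col="gene_id", comment="#",
                        float_precision="round_trip")
    avg_cols = [c for c in table.columns if c.startswith("avg_") and c.endswith("h")]
    averages = table[avg_cols].copy()
    averages.columns = [float(c[4:-1]) for c in avg_cols]
    return ProfileSet(averages)
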