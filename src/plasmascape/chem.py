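"""Lipid normalization of plasma δ13C and lipid-content flagging.

Plasma lipids are depleted in 13C, so lipid-rich samples (C:N mass ratio
above 3.5) read artificially low δ13C. Where both a raw and a delipidated
aliquot of the same sample were measured, per-species differences

    Δδ13C = δ13C_del − δ13C_raw,    ΔC:N = C:N_del − C:N_raw

are regressed (OLS of Δδ13C on ΔC:N) giving a slope m and intercept c. For
samples with no delipidated counterpart the correction is evaluated at
ΔC:N* = mean(C:N_del) − C:N_raw and added back to the raw value:

    δ13C_cor = δ13C_raw + m·ΔC:N* + c            (direct form, default)
    δ13C_cor = δ13C_raw + (ΔC:N* + c) / m        (inverse form, selectable)

The two algebraic forms of the correction generally disagree; both are kept
because published formulations of this normalization differ. δ15N is always
taken from raw plasma and is never altered by the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (AlreadyDelipidatedError, InsufficientDataError,
                     ModelMissingError, SingularFitError)

#: C:N mass ratio above which aquatic-animal tissue is considered lipid-rich
HIGH_LIPID_CN = 3.5

FORMS = ("direct", "printed-inverse")


@dataclass
class PlasmaSample:
    """One individual's blood-plasma isotope measurements."""

    individual_id: str
    species: str
    d13c_raw: float
    d15n: float
    cn_raw: float
    d13c_del: Optional[float] = None
    cn_del: Optional[float] = None
    blood_time: Optional[pd.Timestamp] = None
    truth: dict = field(default_factory=dict)  # synthetic ground truth, if any

    @property
    def has_delipidated(self) -> bool:
        return self.d13c_del is not None and not pd.isna(self.d13c_del)


@dataclass
class NormalizationModel:
    """Fitted species-specific lipid-normalization coefficients."""

    species: str
    m: float
    c: float
    mean_cn_del: float
    n: int
    form: str = "direct"


class LipidNormalization(BaseEstimator):
    """Species lipid-normalization model with a scikit-learn surface.

    ``fit`` takes a frame of paired raw/delipidated measurements (columns
    ``d13c_raw, d13c_del, cn_raw, cn_del``); ``transform`` corrects a frame
    of raw-only samples (columns ``d13c_raw, cn_raw``) and returns corrected
    δ13C values.

    Parameters
    ----------
    form : "direct" or "printed-inverse" — which algebraic form of the
        correction to apply (the fit itself is always the OLS of Δδ13C on
        ΔC:N).
    """

    def __init__(self, form: str = "direct", species: str = ""):
        self.form = form
        self.species = species

    def fit(self, X: pd.DataFrame, y=None):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        pairs = X.dropna(subset=["d13c_raw", "d13c_del", "cn_raw", "cn_del"])
        if len(pairs) < 3:
            raise InsufficientDataError(
                f"{self.species or 'species'}: need >= 3 raw/delipidated pairs")
        ddc = pairs["d13c_del"].to_numpy(float) - pairs["d13c_raw"].to_numpy(float)
        dcn = pairs["cn_del"].to_numpy(float) - pairs["cn_raw"].to_numpy(float)
        if np.ptp(dcn) == 0:
            raise SingularFitError("zero variance in delta C:N")
        res = stats.linregress(dcn, ddc)
        self.m_ = float(res.slope)
        self.c_ = float(res.intercept)
        self.mean_cn_del_ = float(pairs["cn_del"].mean())
        self.n_ = int(len(pairs))
        return self

    def correction(self, cn_raw) -> np.ndarray:
        """Δδ13C to add to a raw value with the given C:N."""
        dcn = self.mean_cn_del_ - np.asarray(cn_raw, float)
        if self.form == "direct":
            return self.m_ * dcn + self.c_
        if self.m_ == 0:
            raise SingularFitError("inverse form undefined for m = 0")
        return (dcn + self.c_) / self.m_

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return X["d13c_raw"].to_numpy(float) + self.correction(X["cn_raw"])

    def to_model(self) -> NormalizationModel:
        return NormalizationModel(self.species, self.m_, self.c_,
                                  self.mean_cn_del_, self.n_, self.form)


def fit_normalization(pairs: pd.DataFrame, form: str = "direct",
                      species: str = "") -> NormalizationModel:
    """OLS of Δδ13C on ΔC:N over paired samples; see module docstring."""
    est = LipidNormalization(form=form, species=species).fit(pairs)
    return est.to_model()


def correct_delta13c(sample: PlasmaSample, model: NormalizationModel) -> float:
    """Lipid-corrected δ13C for a raw-only sample under a fitted model.

    Refuses samples that already have a measured delipidated value (use it
    instead) and models fitted for another species.
    """
    if sample.has_delipidated:
        raise AlreadyDelipidatedError(
            f"{sample.individual_id} has a measured delipidated value")
    if model.species and sample.species and model.species != sample.species:
        raise ModelMissingError(
            f"model for {model.species!r} cannot correct {sample.species!r}")
    est = LipidNormalization(form=model.form, species=model.species)
    est.m_, est.c_, est.mean_cn_del_ = model.m, model.c, model.mean_cn_del
    return float(sample.d13c_raw + est.correction(sample.cn_raw))


def flag_high_lipid(sample: PlasmaSample) -> bool:
    """True iff raw C:N mass ratio exceeds 3.5 (strict)."""
    return float(sample.cn_raw) > HIGH_LIPID_CN


def read_plasma_csv(path) -> pd.DataFrame:
    """Read the isotope dialect ``id,species,d13c_raw,d13c_del,d15n,cn_raw,cn_del,blood_time``."""
    df = pd.read_csv(path)
    df["blood_time"] = pd.to_datetime(df["blood_time"], utc=True).dt.tz_localize(None)
    return df


def samples_from_frame(df: pd.DataFrame) -> list[PlasmaSample]:
    out = []
    for _, r in df.iterrows():
        out.append(PlasmaSample(
            individual_id=str(r["id"]), species=str(r["species"]),
            d13c_raw=float(r["d13c_raw"]), d15n=float(r["d15n"]),
            cn_raw=float(r["cn_raw"]),
            d13c_del=None if pd.isna(r.get("d13c_del")) else float(r["d13c_del"]),
            cn_del=None if pd.isna(r.get("cn_del")) else float(r["cn_del"]),
            blood_time=r.get("blood_time")))
    return out
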