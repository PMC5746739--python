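"""Processing of GC-MS fragment mass-isotopomer data.

Measured mass envelopes of derivatized amino-acid fragments include
contributions from naturally occurring heavy isotopes of every atom that is
not a backbone carbon (the tBDMS derivative's C, H, Si; the fragment's N, O,
S; plus 2H on backbone positions is ignored at this resolution).  Correction
deconvolves that envelope to recover the backbone carbon MID.  The module
also computes fractional enrichment, applies the ion-count reliability
filter, and averages measurement sets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .simulate import FragmentTarget, MIDVector

__all__ = [
    "ISOTOPE_TABLE",
    "FragmentSpec",
    "CorrectionMatrix",
    "MeasurementSet",
    "QCRule",
    "build_correction_matrix",
    "correct_natural_abundance",
    "fractional_enrichment",
    "filter_by_ion_count",
    "average_measurement_sets",
]

#: per-element mass-shift distributions of the stable heavy isotopes
#: (index = extra mass units relative to the lightest isotope)
ISOTOPE_TABLE: dict[str, np.ndarray] = {
    "C": np.array([1 - 0.01109, 0.01109]),
    "H": np.array([1 - 0.000115, 0.000115]),
    "N": np.array([1 - 0.00364, 0.00364]),
    "O": np.array([1 - 0.00038 - 0.00205, 0.00038, 0.00205]),
    "Si": np.array([1 - 0.04685 - 0.03092, 0.04685, 0.03092]),
    "S": np.array([1 - 0.0075 - 0.0425, 0.0075, 0.0425]),
}


@dataclass(frozen=True)
class FragmentSpec:
    """A derivatized amino-acid fragment detected by GC-MS.

    ``backbone_carbons`` are the amino-acid carbon positions the ion retains;
    ``composition`` is the elemental composition of the detected ion
    *excluding* those backbone carbons (it is what the correction matrix is
    built from).
    """

    id: str
    amino_acid: str
    backbone_carbons: tuple[int, ...]
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.backbone_carbons:
            raise ValueError(f"{self.id}: empty backbone carbon set")
        for el, n in self.composition.items():
            if n < 0:
                raise ValueError(f"{self.id}: negative {el} count")

    @property
    def n_carbons(self) -> int:
        return len(self.backbone_carbons)


@dataclass
class CorrectionMatrix:
    fragment_id: str
    matrix: np.ndarray  # (n+1, n+1): backbone MID -> observed envelope (truncated)
    envelope: np.ndarray  # natural-abundance distribution of non-backbone atoms

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def natural_envelope(composition: dict[str, int]) -> np.ndarray:
    """Mass-shift distribution of a set of atoms at natural abundance."""
    env = np.array([1.0])
    for el, n in composition.items():
        if el not in ISOTOPE_TABLE:
            raise ValueError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative {el} count")
        for _ in range(int(n)):
            env = np.convolve(env, ISOTOPE_TABLE[el])
    return env


def build_correction_matrix(frag: FragmentSpec) -> CorrectionMatrix:
    """Convolution matrix of the fragment's non-backbone isotope envelope.

    Column j holds the observed mass-shift distribution of molecules whose
    backbone carries j heavy carbons, truncated to the n+1 masses actually
    recorded; a fragment with no non-backbone atoms gives the identity.
    """
    n = frag.n_carbons
    env = natural_envelope(frag.composition)
    M = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        seg = env[: n + 1 - j]
        M[j : j + len(seg), j] = seg
    return CorrectionMatrix(frag.id, M, env)


def convolve_mid(mid: np.ndarray, frag: FragmentSpec, length: int | None = None) -> np.ndarray:
    """Forward-convolve a backbone MID with the fragment's isotope envelope."""
    full = np.convolve(np.asarray(mid, dtype=float), natural_envelope(frag.composition))
    if length is not None:
        full = full[:length]
    return full


# ---------------------------------------------------------------------------
# measurement sets

@dataclass
class QCRule:
    min_ion_count: float = 1e5

    def __post_init__(self):
        if self.min_ion_count <= 0:
            raise ValueError("ion-count threshold must be positive")


@dataclass
class MeasurementSet:
    """Tabular labelling measurements: the currency of the pipeline.

    ``df`` is long-format with columns ``fragment_id``, ``index`` ("M0".."Mn"
    for mass isotopomers, a binary pattern for positional isotopomers),
    ``value``, ``sd``, ``ion_count``.  ``kind`` is "mid" or "isotopomer".
    ``targets`` maps fragment ids to the simulation targets needed to fit the
    data; ``fragments`` (optional) carries FragmentSpec chemistry.
    """

    df: pd.DataFrame
    kind: str = "mid"
    targets: dict[str, FragmentTarget] = field(default_factory=dict)
    fragments: dict[str, FragmentSpec] = field(default_factory=dict)

    REQUIRED = ("fragment_id", "index", "value", "sd", "ion_count")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"missing column {col!r}")
        self.df = self.df.reset_index(drop=True)

    def fragment_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["fragment_id"]))

    def vector(self, fragment_id: str) -> np.ndarray:
        sub = self.df[self.df["fragment_id"] == fragment_id]
        return sub["value"].to_numpy()

    def mid(self, fragment_id: str) -> MIDVector:
        return MIDVector(fragment_id, self.vector(fragment_id))

    def copy(self) -> "MeasurementSet":
        return MeasurementSet(
            self.df.copy(), self.kind, dict(self.targets), dict(self.fragments)
        )

    def assign_sd(self, rel: float = 0.01, floor: float = 0.001) -> "MeasurementSet":
        """Nominal SD rule: sd = max(rel * |value|, floor)."""
        out = self.copy()
        out.df["sd"] = np.maximum(rel * out.df["value"].abs(), floor)
        return out

    @classmethod
    def from_mids(
        cls,
        mids: list[MIDVector],
        targets: dict[str, FragmentTarget] | None = None,
        fragments: dict[str, FragmentSpec] | None = None,
        sd: float = 0.001,
        ion_count: float = 1e6,
    ) -> "MeasurementSet":
        rows = []
        for m in mids:
            for i, v in enumerate(m.abundances):
                rows.append((m.fragment_id, f"M{i}", float(v), sd, ion_count))
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(df, "mid", targets or {}, fragments or {})

    @classmethod
    def from_isotopomers(cls, dists, sd: float = 0.001) -> "MeasurementSet":
        from .simulate import index_pattern

        rows = []
        for d in dists:
            n = d.n_carbons
            for idx, v in enumerate(d.abundances):
                rows.append((d.metabolite, index_pattern(idx, n), float(v), sd, 1e6))
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(df, "isotopomer")

    def with_flux_measurements(
        self, fluxes: dict[str, float], sd: float | None = None
    ) -> "MeasurementSet":
        """Append direct rate measurements (e.g. substrate uptake).

        Labelling patterns constrain only flux ratios; at least one measured
        rate is needed to pin the absolute scale.  Rows carry the sentinel
        fragment id ``@flux`` with the reaction name in ``index``.
        """
        rows = [
            (
                "@flux",
                name,
                float(v),
                sd if sd is not None else max(0.01 * abs(v), 0.001),
                np.inf,
            )
            for name, v in fluxes.items()
        ]
        out = self.copy()
        out.df = pd.concat(
            [out.df, pd.DataFrame(rows, columns=list(self.REQUIRED))],
            ignore_index=True,
        )
        return out

    def to_tsv(self, path_or_buf=None):
        return self.df.to_csv(path_or_buf, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path_or_buf, kind: str = "mid") -> "MeasurementSet":
        if isinstance(path_or_buf, str) and "\t" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        df = pd.read_csv(path_or_buf, sep="\t", dtype={"index": str})
        return cls(df, kind)


def fractional_enrichment(mid) -> float:
    """Mean 13C fraction per carbon: sum(i * Mi) / n.

    Accepts a MIDVector or a raw abundance array.  Noisy inputs may carry
    negative entries after baseline correction; the value is returned
    unclamped and may be negative.
    """
    a = mid.abundances if isinstance(mid, MIDVector) else np.asarray(mid, dtype=float)
    n = len(a) - 1
    if n == 0:
        return 0.0
    weights = np.arange(n + 1)
    return float((weights @ a) / n)


def correct_natural_abundance(
    raw: MeasurementSet,
    matrices: dict[str, CorrectionMatrix] | None = None,
    clamp: bool = False,
    cond_limit: float = 1e8,
) -> MeasurementSet:
    """Deconvolve non-backbone natural abundance from raw mass envelopes.

    Solves ``M x = y`` per fragment by least squares (bounded to [0, 1] when
    ``clamp`` is set) and renormalizes the corrected MID to sum 1.  Negative
    corrected abundances are retained by default: they carry the statistical
    signature of baseline-corrected low-count signals.
    """
    import warnings

    if matrices is None:
        matrices = {
            fid: build_correction_matrix(spec) for fid, spec in raw.fragments.items()
        }
    out = raw.copy()
    for fid in out.fragment_ids():
        mask = out.df["fragment_id"] == fid
        y = out.df.loc[mask, "value"].to_numpy()
        if fid not in matrices:
            raise KeyError(f"no correction matrix for fragment {fid}")
        cm = matrices[fid]
        n1 = cm.matrix.shape[0]
        if len(y) < n1:
            raise ValueError(f"{fid}: raw envelope shorter than backbone MID")
        y = y[:n1]
        if np.all(y == 0):
            raise ValueError(f"{fid}: empty spectrum")
        if cm.condition_number > cond_limit:
            warnings.warn(
                f"{fid}: ill-conditioned correction matrix "
                f"(cond={cm.condition_number:.2g})",
                stacklevel=2,
            )
        if clamp:
            x = lsq_linear(cm.matrix, y, bounds=(0.0, 1.0)).x
        else:
            x, *_ = np.linalg.lstsq(cm.matrix, y, rcond=None)
        total = x.sum()
        if total != 0:
            x = x / total
        rows = out.df.index[mask][:n1]
        out.df.loc[rows, "value"] = x
        out.df.loc[out.df.index[mask][n1:], "value"] = np.nan
        out.df.loc[rows, "index"] = [f"M{i}" for i in range(n1)]
    out.df = out.df.dropna(subset=["value"]).reset_index(drop=True)
    return out


def filter_by_ion_count(ms: MeasurementSet, rule: QCRule) -> MeasurementSet:
    """Drop fragments whose total ion count falls below the QC threshold."""
    import logging

    keep = ms.df["ion_count"] >= rule.min_ion_count
    removed = ms.df.loc[~keep, "fragment_id"].nunique()
    if removed:
        logging.getLogger(__name__).info(
            "ion-count filter removed %d fragment(s) below %g",
            removed,
            rule.min_ion_count,
        )
    out = ms.copy()
    out.df = ms.df.loc[keep].reset_index(drop=True)
    return out


def average_measurement_sets(
    sets: list[MeasurementSet], weights=None
) -> MeasurementSet:
    """Weighted per-isotopomer average of identically-panelled datasets."""
    if not sets:
        raise ValueError("no measurement sets")
    if weights is None:
        weights = np.full(len(sets), 1.0 / len(sets))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(sets):
        raise ValueError("weights and sets differ in length")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")

    ref = sets[0]
    key_ref = list(zip(ref.df["fragment_id"], ref.df["index"]))
    for other in sets[1:]:
        key_other = list(zip(other.df["fragment_id"], other.df["index"]))
        if key_ref != key_other:
            missing = set(key_ref) ^ set(key_other)
            raise ValueError(f"fragment panels differ: {sorted(missing)[:5]} ...")
    out = ref.copy()
    out.df["value"] = sum(
        w * s.df["value"].to_numpy() for w, s in zip(weights, sets)
    )
    out.df["sd"] = np.sqrt(
        sum((w * s.df["sd"].to_numpy()) ** 2 for w, s in zip(weights, sets))
    )
    out.df["ion_count"] = sum(
        w * s.df["ion_count"].to_numpy() for w, s in zip(weights, sets)
    )
    return out
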