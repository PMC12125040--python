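"""Reading and annotating deconvolved GC-MS peak tables.

The front end of the pipeline: per-sample peak lists (one row per resolved
chromatographic peak) are calibrated against a per-batch C6-C40 n-alkane
ladder to obtain linear (Kovats-scale) retention indices, the spiked
internal standard (2-acetoxytetradecane) is located in every sample, and
peak intensities are re-expressed as relative amounts (intensity divided by
the internal-standard intensity of the same sample).

Input dialects
--------------
Peak table : CSV ``sample_id,batch_id,rt_min,intensity,mz1,mz2``
             (``mz1`` is the most intense fragment ion).
Ladder     : CSV ``batch_id,carbon_number,rt_min``.
Metadata   : CSV ``sample_id,species,subspecies,subclade,genus_group,
             mating_strategy,sex,rearing,batch_id``.

Peaks eluting outside the span of the available ladder rungs are rejected
rather than extrapolated; samples without an unambiguous internal-standard
peak are excluded, with the reason logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("blendevol")

#: The nine Heliconiini subclade labels used for clade-level contrasts.
SUBCLADES = (
    "basal",
    "Eueides",
    "erato",
    "sara/sapho",
    "aoede",
    "doris",
    "wallacei",
    "silvaniform",
    "melpomene",
)

GENUS_GROUPS = ("Heliconius", "Eueides", "basal")

PEAK_COLUMNS = ["sample_id", "batch_id", "rt_min", "intensity", "mz1", "mz2"]
META_COLUMNS = [
    "sample_id",
    "species",
    "subspecies",
    "subclade",
    "genus_group",
    "mating_strategy",
    "sex",
    "rearing",
    "batch_id",
]


class ValidationError(ValueError):
    """Malformed or contract-violating input."""


class CalibrationRangeError(ValidationError):
    """Retention time outside the span of the alkane ladder."""


class InternalStandardError(ValidationError):
    """No usable internal-standard peak in a sample."""


class InternalStandardTieError(InternalStandardError):
    """Two candidate internal-standard peaks equally close in RI."""


class DegenerateStatisticError(ValueError):
    """A statistic is undefined for the given (degenerate) input."""


@dataclass(frozen=True)
class AlkaneLadder:
    """Per-batch retention times of the C6-C40 n-alkane standard mixture.

    ``rungs`` maps carbon number n (6..40) to retention time in minutes.
    Retention times must increase strictly with carbon number and at least
    two rungs must be present for interpolation.
    """

    batch_id: str
    rungs: dict[int, float]

    def __post_init__(self) -> None:
        if len(self.rungs) < 2:
            raise ValidationError(
                f"ladder {self.batch_id!r}: need at least two rungs, "
                f"got {len(self.rungs)}"
            )
        ns = sorted(self.rungs)
        if ns[0] < 6 or ns[-1] > 40:
            raise ValidationError(
                f"ladder {self.batch_id!r}: carbon numbers must lie in 6..40"
            )
        rts = [self.rungs[n] for n in ns]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValidationError(
                f"ladder {self.batch_id!r}: retention times must increase "
                "strictly with carbon number"
            )

    @property
    def carbon_numbers(self) -> list[int]:
        return sorted(self.rungs)

    @property
    def span(self) -> tuple[float, float]:
        ns = self.carbon_numbers
        return self.rungs[ns[0]], self.rungs[ns[-1]]


@dataclass(frozen=True)
class InternalStandardConfig:
    """Where to look for the spiked internal standard in each chromatogram.

    The standard is recognised by its fragment ion pair and a retention-index
    window (``ri_center`` +/- ``ri_window``); among multiple in-window
    candidates the one closest in RI to the centre wins, and an exact tie is
    an error rather than a guess. Defaults describe 2-acetoxytetradecane
    (acetate ester fragments m/z 43 and 61, RI ~1585 on an apolar column).
    """

    ri_center: float = 1585.0
    ri_window: float = 15.0
    top_ions: tuple[int, int] = (43, 61)
    require_ion_match: bool = True

    def ion_set(self) -> frozenset[int]:
        return frozenset(self.top_ions)


# ---------------------------------------------------------------------------
# readers

def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a deconvolved peak table CSV."""
    df = pd.read_csv(path)
    return validate_peak_table(df)


def validate_peak_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"peak table missing columns: {missing}")
    df = df[PEAK_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["batch_id"] = df["batch_id"].astype(str)
    if (df["rt_min"] <= 0).any():
        raise ValidationError("retention times must be positive")
    if (df["intensity"] < 0).any():
        raise ValidationError("intensities must be nonnegative")
    for col in ("mz1", "mz2"):
        vals = df[col].to_numpy()
        if not np.all(np.equal(np.mod(vals, 1), 0)) or (vals <= 0).any():
            raise ValidationError(f"{col} must hold positive integer m/z values")
        df[col] = df[col].astype(int)
    return df


def read_ladders(path) -> dict[str, AlkaneLadder]:
    """Read per-batch alkane ladders from CSV (batch_id,carbon_number,rt_min)."""
    df = pd.read_csv(path)
    missing = [c for c in ("batch_id", "carbon_number", "rt_min") if c not in df.columns]
    if missing:
        raise ValidationError(f"ladder table missing columns: {missing}")
    ladders: dict[str, AlkaneLadder] = {}
    for batch_id, grp in df.groupby(df["batch_id"].astype(str)):
        rungs = dict(zip(grp["carbon_number"].astype(int), grp["rt_min"].astype(float)))
        ladders[batch_id] = AlkaneLadder(batch_id=batch_id, rungs=rungs)
    return ladders


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    df = df[META_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    bad = sorted(set(df["subclade"]) - set(SUBCLADES))
    if bad:
        raise ValidationError(
            f"unknown subclade labels {bad}; expected one of {list(SUBCLADES)}"
        )
    bad = sorted(set(df["genus_group"]) - set(GENUS_GROUPS))
    if bad:
        raise ValidationError(f"unknown genus_group labels {bad}")
    bad = sorted(set(df["mating_strategy"]) - {"pupal", "free", ""})
    if bad:
        raise ValidationError(f"unknown mating_strategy labels {bad}")
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# retention-index calibration

def compute_retention_index(rt: float, ladder: AlkaneLadder) -> float:
    """Linear (Kovats-scale) retention index of a peak at ``rt`` minutes.

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)) where C_n and C_{n+1}
    are the ladder rungs bracketing ``rt``; a rung's own retention time maps
    exactly to 100*n. Retention times outside the ladder span raise
    :class:`CalibrationRangeError` -- no extrapolation.
    """
    ns = ladder.carbon_numbers
    rts = np.array([ladder.rungs[n] for n in ns])
    lo, hi = rts[0], rts[-1]
    if rt < lo or rt > hi:
        raise CalibrationRangeError(
            f"rt {rt:.4f} min outside ladder span [{lo:.4f}, {hi:.4f}] "
            f"of batch {ladder.batch_id!r}"
        )
    # right-most rung with rt_n <= rt; the last rung maps to its own index
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    if i == len(ns) - 1:
        return 100.0 * ns[-1]
    n_lo, n_hi = ns[i], ns[i + 1]
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    return 100.0 * (n_lo + frac * (n_hi - n_lo))


def relative_amount(peak_intensity: float, internal_standard_intensity: float) -> float:
    """Peak intensity expressed relative to the internal standard."""
    if internal_standard_intensity <= 0:
        raise InternalStandardError(
            "internal standard intensity must be positive"
        )
    return peak_intensity / internal_standard_intensity


# ---------------------------------------------------------------------------
# internal standard annotation + full per-sample annotation

def annotate_internal_standard(
    peaks: pd.DataFrame, config: InternalStandardConfig
) -> pd.DataFrame:
    """Flag exactly one internal-standard peak per sample.

    ``peaks`` must already carry a ``retention_index`` column. Candidates
    are peaks whose (unordered) top-ion pair equals the configured pair and
    whose RI lies within the configured window. Ambiguity is resolved by
    closest RI to the window centre; an exact tie raises
    :class:`InternalStandardTieError`. Samples with no candidate raise
    :class:`InternalStandardError` (callers excluding rather than failing
    should catch per sample; see :func:`annotate_peaks`).
    """
    out = peaks.copy()
    out["is_internal_standard"] = False
    for sample_id, grp in out.groupby("sample_id", sort=False):
        idx = _locate_internal_standard(grp, config, sample_id)
        out.loc[idx, "is_internal_standard"] = True
    return out


def _locate_internal_standard(
    grp: pd.DataFrame, config: InternalStandardConfig, sample_id: str
):
    in_window = (grp["retention_index"] - config.ri_center).abs() <= config.ri_window
    cand = grp[in_window]
    if config.require_ion_match:
        ions = config.ion_set()
        mask = [
            frozenset((int(a), int(b))) == ions
            for a, b in zip(cand["mz1"], cand["mz2"])
        ]
        cand = cand[mask]
    if len(cand) == 0:
        raise InternalStandardError(
            f"sample {sample_id!r}: no internal-standard candidate in RI window "
            f"{config.ri_center}±{config.ri_window}"
        )
    if len(cand) == 1:
        return cand.index[0]
    dist = (cand["retention_index"] - config.ri_center).abs().to_numpy()
    order = np.argsort(dist, kind="stable")
    if np.isclose(dist[order[0]], dist[order[1]], rtol=0.0, atol=1e-12):
        raise InternalStandardTieError(
            f"sample {sample_id!r}: two internal-standard candidates equally "
            f"close to RI {config.ri_center}"
        )
    return cand.index[order[0]]


@dataclass
class AnnotationResult:
    """Annotated peaks plus the per-sample exclusion log."""

    peaks: pd.DataFrame
    excluded_samples: dict[str, str] = field(default_factory=dict)
    dropped_out_of_range: int = 0


def annotate_peaks(
    peaks: pd.DataFrame,
    ladders: dict[str, AlkaneLadder],
    is_config: InternalStandardConfig | None = None,
) -> AnnotationResult:
    """Full per-peak annotation: RI, internal standard, relative amounts.

    Peaks outside their batch's ladder span are dropped (logged). Samples
    with a missing or zero-intensity internal standard are excluded entirely,
    with the reason recorded in ``excluded_samples``. An internal-standard
    tie is not guessed around and propagates as an error.
    """
    if is_config is None:
        is_config = InternalStandardConfig()
    df = validate_peak_table(peaks)

    unknown = sorted(set(df["batch_id"]) - set(ladders))
    if unknown:
        raise ValidationError(f"no alkane ladder for batches: {unknown}")

    ri = np.full(len(df), np.nan)
    vals = df[["batch_id", "rt_min"]].itertuples(index=False)
    for k, (batch_id, rt) in enumerate(vals):
        try:
            ri[k] = compute_retention_index(float(rt), ladders[batch_id])
        except CalibrationRangeError:
            pass
    df = df.assign(retention_index=ri)
    n_dropped = int(np.isnan(ri).sum())
    if n_dropped:
        logger.warning("dropped %d peaks outside ladder span", n_dropped)
        df = df[~np.isnan(df["retention_index"])].copy()

    excluded: dict[str, str] = {}
    parts: list[pd.DataFrame] = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        try:
            idx = _locate_internal_standard(grp, is_config, sample_id)
        except InternalStandardTieError:
            raise
        except InternalStandardError as exc:
            excluded[sample_id] = str(exc)
            logger.warning("excluding sample %s: %s", sample_id, exc)
            continue
        is_intensity = float(grp.loc[idx, "intensity"])
        if is_intensity <= 0:
            excluded[sample_id] = "internal standard has zero intensity"
            logger.warning(
                "excluding sample %s: internal standard has zero intensity",
                sample_id,
            )
            continue
        grp = grp.copy()
        grp["is_internal_standard"] = grp.index == idx
        grp["relative_amount"] = grp["intensity"] / is_intensity
        parts.append(grp)

    if not parts:
        raise ValidationError("no sample with a usable internal standard")
    annotated = pd.concat(parts)
    return AnnotationResult(
        peaks=annotated, excluded_samples=excluded, dropped_out_of_range=n_dropped
    )
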