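"""Downstream use of fitted binding models.

Covers extraction of ddG/RT matrices in the reporting gauge, the
log-enrichment (PSSM) baseline computed directly from count tables,
peptide scoring and proteome-wide phosphosite scanning, missense
variant-effect prediction, model comparison and clustering, and
validation regression against measured dissociation constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, pearsonr

from .energy_model import BindingModel, log_specific_affinity, window_energy
from .seqio import AA_ALPHABET, AA_INDEX, CountTable, encode_peptides


@dataclass
class DdgMatrix:
    """Free-energy matrix ddG/RT in the reporting gauge.

    Values are the negated specific-mode coefficients with each free column
    mean-centered, so a positive entry is an unfavourable residue.  Position
    labels run relative to the central residue (-5..+5 for an 11-wide
    matrix).  ``frozen_center`` marks a constraint column reported as-is.
    """

    values: np.ndarray  # (20, width)
    frozen_center: int | None = None

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def position_labels(self) -> list[str]:
        center = self.width // 2
        return [f"{p - center:+d}" if p != center else "0" for p in range(self.width)]

    def free_mask(self) -> np.ndarray:
        mask = np.ones(self.width, dtype=bool)
        if self.frozen_center is not None:
            mask[self.frozen_center] = False
        return mask

    def flatten_free(self) -> np.ndarray:
        return self.values[:, self.free_mask()].ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(AA_ALPHABET), columns=self.position_labels()
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="residue")

    @classmethod
    def from_tsv(cls, path, frozen_center: int | None = None) -> "DdgMatrix":
        df = pd.read_csv(path, sep="\t", index_col="residue")
        if list(df.index) != list(AA_ALPHABET):
            df = df.loc[list(AA_ALPHABET)]
        return cls(df.to_numpy(dtype=float), frozen_center)


@dataclass
class ScoredSite:
    site_id: str
    peptide: str
    log_affinity: float


@dataclass
class VariantEffect:
    site_id: str
    wt_peptide: str
    var_peptide: str
    log_ratio: float
    max_log_affinity: float
    direction: str  # gain / loss / neutral


def ddg_matrix(model: BindingModel) -> DdgMatrix:
    """Extract ddG/RT from a fitted model: negate and mean-center free columns."""
    beta = model.specific.coeffs
    values = -beta.copy()
    free = model.specific.free_column_mask()
    values[:, free] -= values[:, free].mean(axis=0, keepdims=True)
    frozen = model.specific.center_index if model.specific.constrained else None
    return DdgMatrix(values, frozen)


def enrichment_matrix(
    input_table: CountTable,
    bound_table: CountTable | None = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Per-position amino-acid log-enrichment between bound and input libraries.

    Entry (a, p) is ln of the ratio of the (pseudocount-adjusted) frequency
    of residue ``a`` at position ``p`` in the bound library to that in the
    input library.  This is the PSSM baseline that free-energy regression
    improves on: it conflates all binding offsets and non-specific capture.
    """
    if bound_table is None:
        bound_table = input_table
    if input_table.seq_len != bound_table.seq_len:
        raise ValueError("tables must share sequence length")
    L = input_table.seq_len
    n_aa = len(AA_ALPHABET)

    def _freqs(table: CountTable, counts: np.ndarray) -> np.ndarray:
        enc = encode_peptides(table.sequences)
        mat = np.zeros((n_aa, L))
        for p in range(L):
            mat[:, p] = np.bincount(enc[:, p], weights=counts.astype(float), minlength=n_aa)
        mat += pseudocount
        totals = mat.sum(axis=0, keepdims=True)
        if (totals == 0).any():
            raise ValueError("zero column total with zero pseudocount")
        return mat / totals

    f_in = _freqs(input_table, input_table.input_counts)
    f_bd = _freqs(bound_table, bound_table.bound_counts)
    if ((f_in == 0) & (f_bd > 0)).any():
        raise ValueError("residue enriched from zero input frequency; use a pseudocount")
    with np.errstate(divide="ignore", invalid="ignore"):
        # cells absent from both libraries are undefined, reported as NaN
        return np.log(f_bd / f_in)


def score_peptide(model: BindingModel, peptide: str, mode: str = "total") -> float:
    """Predicted log relative affinity of a peptide.

    ``total`` sums over all binding offsets (controls for non-central
    tyrosines); ``central`` scores only the window centered on the middle
    residue.
    """
    if len(peptide) != model.var_len:
        raise ValueError("peptide length must equal model var_len")
    if mode == "total":
        return float(log_specific_affinity(model, encode_peptides([peptide]))[0])
    if mode == "central":
        w = model.specific.width
        padded = model.flank_left + peptide + model.flank_right
        center = len(model.flank_left) + model.var_len // 2
        window = padded[center - w // 2 : center + w // 2 + 1]
        return window_energy(model.specific, window)
    raise ValueError(f"unknown scoring mode {mode!r}")


def scan_sites(
    model: BindingModel,
    sites: list[tuple[str, str]],
    keep_ids: set[str] | None = None,
    mode: str = "total",
) -> list[ScoredSite]:
    """Score phosphosite peptides, filter, and rank by predicted affinity.

    ``keep_ids`` implements upstream filters (e.g. co-expression with the
    relevant kinase) computed by the user.  Output is sorted by descending
    log affinity with lexicographic site-id tie-breaking.
    """
    out = []
    for site_id, peptide in sites:
        if keep_ids is not None and site_id not in keep_ids:
            continue
        out.append(ScoredSite(site_id, peptide, score_peptide(model, peptide, mode)))
    out.sort(key=lambda s: (-s.log_affinity, s.site_id))
    return out


def variant_effect(
    model: BindingModel,
    site_id: str,
    wt_peptide: str,
    var_peptide: str,
    mode: str = "total",
    neutral_band: float = 0.1,
) -> VariantEffect:
    """Predicted allelic effect of a missense variant in a binding site.

    ``log_ratio`` is the variant-minus-wild-type log affinity; positive
    means the variant binds tighter (gain).  Variants substituting the
    central (phospho-acceptor) residue are rejected — the model cannot
    meaningfully compare a site that loses its anchor.
    """
    if len(wt_peptide) != len(var_peptide):
        raise ValueError("alleles must have equal length")
    if wt_peptide == var_peptide:
        raise ValueError("alleles are identical")
    center = model.var_len // 2
    if wt_peptide[center] != var_peptide[center]:
        raise ValueError("substitution of the central residue is not scoreable")
    wt = score_peptide(model, wt_peptide, mode)
    var = score_peptide(model, var_peptide, mode)
    log_ratio = var - wt
    if log_ratio > neutral_band:
        direction = "gain"
    elif log_ratio < -neutral_band:
        direction = "loss"
    else:
        direction = "neutral"
    return VariantEffect(site_id, wt_peptide, var_peptide, log_ratio, max(wt, var), direction)


def compare_models(
    a: DdgMatrix | np.ndarray,
    b: DdgMatrix | np.ndarray,
    exclude_center: bool = True,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Squared Pearson correlation between two coefficient matrices.

    Frozen/center columns are excluded by default since constraint values
    carry no fitted information.
    """
    def _flat(m, other):
        if isinstance(m, DdgMatrix):
            mask = m.free_mask() if exclude_center else np.ones(m.width, bool)
            return m.values, mask
        m = np.asarray(m, dtype=float)
        mask = np.ones(m.shape[1], dtype=bool)
        if exclude_center:
            center = None
            for x in (a, b):
                if isinstance(x, DdgMatrix) and x.frozen_center is not None:
                    center = x.frozen_center
            if center is not None:
                mask[center] = False
        return m, mask

    va, mask_a = _flat(a, b)
    vb, mask_b = _flat(b, a)
    if va.shape != vb.shape:
        raise ValueError("matrices must share shape")
    mask = mask_a & mask_b
    xs, ys = va[:, mask].ravel(), vb[:, mask].ravel()
    r = pearsonr(xs, ys).statistic
    return float(r**2), xs, ys


def centered_rmse(estimate: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """RMSE after mean-centering each column of both matrices.

    Column centering removes the gauge/composition offset so that matrices
    on different absolute scales of per-position preference are comparable.
    """
    if mask is None:
        mask = np.ones(truth.shape[1], dtype=bool)
    e = estimate[:, mask] - estimate[:, mask].mean(axis=0, keepdims=True)
    t = truth[:, mask] - truth[:, mask].mean(axis=0, keepdims=True)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def fit_kd_regression(
    predicted: np.ndarray, measured_kd: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least squares of ln(K_D) on predicted ddG/RT scores.

    Returns (slope, intercept, r2).  An additive energy model predicts
    ln K_D up to an affine transform, so slope and r2 quantify how well
    the fitted matrix captures measured affinities.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured_kd = np.asarray(measured_kd, dtype=float)
    if len(predicted) != len(measured_kd) or len(predicted) < 3:
        raise ValueError("need >= 3 paired observations")
    if (measured_kd <= 0).any():
        raise ValueError("K_D values must be positive")
    if np.allclose(predicted, predicted[0]):
        raise ValueError("degenerate regressor: constant predictions")
    res = linregress(predicted, np.log(measured_kd))
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def cluster_models(models: list[DdgMatrix]) -> np.ndarray:
    """Average-linkage hierarchical clustering of energy matrices.

    Distance is 1 - Pearson correlation over the flattened free (non-center)
    entries.  Returns a scipy linkage matrix.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    flats = [m.flatten_free() for m in models]
    shapes = {f.shape for f in flats}
    if len(shapes) > 1:
        raise ValueError("models must share shape")
    n = len(flats)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pearsonr(flats[i], flats[j]).statistic
            dist[i, j] = dist[j, i] = 1.0 - r
    return linkage(squareform(dist, checks=False), method="average")


def plot_energy_logo(matrix: DdgMatrix, ax=None, flip: bool = True):
    """Thin convenience rendering of an energy matrix as stacked letters.

    Letter height is the magnitude of -ddG/RT (favourable residues up when
    ``flip``).  For publication-quality logos export the matrix with
    ``to_tsv`` and use a dedicated logo tool.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * matrix.width, 2.5))
    vals = -matrix.values if flip else matrix.values
    for p in range(matrix.width):
        col = vals[:, p]
        order = np.argsort(col)
        y_pos, y_neg = 0.0, 0.0
        for idx in order[::-1]:
            h = col[idx]
            if h >= 0:
                ax.text(p, y_pos, AA_ALPHABET[idx], ha="center", va="bottom",
                        fontsize=6 + 10 * min(abs(h), 2), alpha=min(1.0, 0.3 + abs(h)))
                y_pos += max(h, 0.05)
            else:
                y_neg -= max(-h, 0.05)
                ax.text(p, y_neg, AA_ALPHABET[idx], ha="center", va="top",
                        fontsize=6 + 10 * min(abs(h), 2), alpha=min(1.0, 0.3 + abs(h)))
    ax.set_xticks(range(matrix.width), matrix.position_labels())
    ax.set_xlabel("position relative to central residue")
    ax.set_ylabel("-ddG/RT")
    return ax


def read_sites_tsv(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["site_id"], df["peptide"]))


def read_variants_tsv(path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["site_id"], df["peptide"], df["var_peptide"]))


def scored_sites_to_frame(sites: list[ScoredSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "peptide": [s.peptide for s in sites],
            "log_affinity": [s.log_affinity for s in sites],
        }
    )


def variant_effects_to_frame(effects: list[VariantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_id": [e.site_id for e in effects],
            "peptide": [e.wt_peptide for e in effects],
            "var_peptide": [e.var_peptide for e in effects],
            "log_ratio": [e.log_ratio for e in effects],
            "max_log_affinity": [e.max_log_affinity for e in effects],
            "direction": [e.direction for e in effects],
        }
    )
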