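"""Two-binding-mode enrichment model for affinity-selection count data.

The predicted enrichment of a peptide in the bound library is a sum of two
"binding mode" terms: a sequence-specific mode scoring every possible
binding-site offset (including offsets that overlap the constant flanking
residues of the display scaffold), and a non-specific mode with short
windows plus a positional bias that absorbs experimental artefacts:

    kappa_c(s) = alpha_{c,NS} * sum_x exp(X(s, x:x+w_NS) . beta_NS + gamma_x)
               + alpha_{c,S}  * sum_x exp(X(s, x:x+w_S)  . beta_S)

Coefficients are log-fold binding effects, so the entries of ``beta_S`` are
-ddG/RT: the additive free-energy matrix the regression aims to learn.
Each count table (one per selection round) is modelled as a single-round
SELEX experiment via a scaled binomial log-likelihood over the input/bound
read split of every observed sequence.

All affinity computations run in log space so that large coefficient
magnitudes (e.g. the -10 penalty of the central-tyrosine constraint)
cannot overflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .seqio import AA_ALPHABET, AA_INDEX, CountTable, encode_peptides

N_AA = len(AA_ALPHABET)


@dataclass
class EnergyMatrix:
    """Additive residue-by-position coefficient matrix (one binding mode).

    ``coeffs`` has shape (20, width) over the alphabetically ordered
    canonical amino acids.  When ``constrained`` the central column is frozen
    to 0 for the anchor residue (tyrosine by default) and -10 for all other
    residues, focusing the mode on sites anchored at that residue.
    """

    width: int
    coeffs: np.ndarray = None
    center_index: int | None = None
    constrained: bool = False

    def __post_init__(self) -> None:
        if self.coeffs is None:
            self.coeffs = np.zeros((N_AA, self.width))
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (N_AA, self.width):
            raise ValueError(f"coeffs must have shape ({N_AA}, {self.width})")

    def copy(self) -> "EnergyMatrix":
        return EnergyMatrix(self.width, self.coeffs.copy(), self.center_index, self.constrained)

    def free_column_mask(self) -> np.ndarray:
        """Boolean mask over columns that are optimizer-adjustable."""
        mask = np.ones(self.width, dtype=bool)
        if self.constrained and self.center_index is not None:
            mask[self.center_index] = False
        return mask


@dataclass
class NonSpecificMode:
    """Short-window mode with per-offset bias absorbing sequence artefacts."""

    matrix: EnergyMatrix
    positional_bias: np.ndarray = None  # gamma_x, one entry per window offset

    def __post_init__(self) -> None:
        if self.positional_bias is not None:
            self.positional_bias = np.asarray(self.positional_bias, dtype=float)

    def n_offsets(self, var_len: int) -> int:
        return var_len - self.matrix.width + 1

    def bias(self, var_len: int) -> np.ndarray:
        if self.positional_bias is None:
            return np.zeros(self.n_offsets(var_len))
        if len(self.positional_bias) != self.n_offsets(var_len):
            raise ValueError("positional bias length does not match offset count")
        return self.positional_bias


@dataclass
class BindingModel:
    """Full selection model: two modes plus per-table scale parameters.

    ``activities[c] = (alpha_NS, alpha_S)`` sets the contribution of each
    mode in count table ``c``; ``depth_params[c] = (eta_I, eta_B)`` controls
    the relative sequencing depth of the input and bound columns in the
    binomial likelihood.  ``eta_B`` is redundant with the activities and is
    conventionally fixed to 1.
    """

    specific: EnergyMatrix
    nonspecific: NonSpecificMode
    flank_left: str = "GQSGQ"
    flank_right: str = "GGQSG"
    flank_overlap: int = 5  # f_S: flank residues a specific-mode window may cover
    var_len: int = 11
    activities: list[tuple[float, float]] = field(default_factory=list)
    depth_params: list[tuple[float, float]] = field(default_factory=list)
    round_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a_ns, a_s in self.activities:
            if a_ns <= 0 or a_s <= 0:
                raise ValueError("activities must be strictly positive")
        for e_i, e_b in self.depth_params:
            if e_i <= 0 or e_b <= 0:
                raise ValueError("depth parameters must be strictly positive")

    @property
    def n_tables(self) -> int:
        return len(self.activities)

    def n_specific_offsets(self) -> int:
        return self.var_len + 2 * self.flank_overlap - self.specific.width + 1

    def copy(self) -> "BindingModel":
        ns = NonSpecificMode(
            self.nonspecific.matrix.copy(),
            None if self.nonspecific.positional_bias is None else self.nonspecific.positional_bias.copy(),
        )
        return BindingModel(
            self.specific.copy(), ns, self.flank_left, self.flank_right,
            self.flank_overlap, self.var_len, list(self.activities),
            list(self.depth_params), list(self.round_labels),
        )


# ---------------------------------------------------------------------------
# window construction and vectorized affinities

def specific_window_indices(encoded: np.ndarray, model: BindingModel) -> np.ndarray:
    """Residue indices of every specific-mode window, shape (n, X_S, w_S).

    Windows slide over the variable region padded with up to
    ``flank_overlap`` residues of the constant flanks on each side.
    """
    n, L = encoded.shape
    if L != model.var_len:
        raise ValueError(f"peptide length {L} != model var_len {model.var_len}")
    fs = model.flank_overlap
    w = model.specific.width
    left = encode_peptides([model.flank_left[len(model.flank_left) - fs:]])[0] if fs else np.zeros(0, np.int8)
    right = encode_peptides([model.flank_right[:fs]])[0] if fs else np.zeros(0, np.int8)
    padded = np.concatenate(
        [np.broadcast_to(left, (n, fs)), encoded, np.broadcast_to(right, (n, fs))], axis=1
    )
    n_off = L + 2 * fs - w + 1
    if n_off < 1:
        raise ValueError("specific matrix wider than padded sequence")
    starts = np.arange(n_off)
    return padded[:, starts[:, None] + np.arange(w)[None, :]]


def nonspecific_window_indices(encoded: np.ndarray, model: BindingModel) -> np.ndarray:
    """Residue indices of non-specific windows (variable region only)."""
    n, L = encoded.shape
    w = model.nonspecific.matrix.width
    starts = np.arange(L - w + 1)
    return encoded[:, starts[:, None] + np.arange(w)[None, :]]


def window_energies(coeffs: np.ndarray, windows: np.ndarray) -> np.ndarray:
    """Sum of per-position coefficients for each window: (n, X) energies."""
    w = windows.shape[-1]
    flat = windows.astype(np.int64) * w + np.arange(w)
    return coeffs.ravel()[flat].sum(axis=-1)


def log_specific_affinity(model: BindingModel, encoded: np.ndarray) -> np.ndarray:
    """ln sum_x exp(window energy) over all specific-mode offsets."""
    e = window_energies(model.specific.coeffs, specific_window_indices(encoded, model))
    return logsumexp(e, axis=-1)


def log_nonspecific_affinity(model: BindingModel, encoded: np.ndarray) -> np.ndarray:
    e = window_energies(
        model.nonspecific.matrix.coeffs, nonspecific_window_indices(encoded, model)
    )
    e = e + model.nonspecific.bias(model.var_len)[None, :]
    return logsumexp(e, axis=-1)


def log_predicted_enrichment(
    model: BindingModel, encoded: np.ndarray, table_index: int
) -> np.ndarray:
    a_ns, a_s = model.activities[table_index]
    return np.logaddexp(
        np.log(a_ns) + log_nonspecific_affinity(model, encoded),
        np.log(a_s) + log_specific_affinity(model, encoded),
    )


# ---------------------------------------------------------------------------
# scalar convenience wrappers

def window_energy(matrix: EnergyMatrix, window: str) -> float:
    """Dot product of the one-hot encoded window with the coefficient matrix."""
    if len(window) != matrix.width:
        raise ValueError("window length must equal matrix width")
    return float(sum(matrix.coeffs[AA_INDEX[a], p] for p, a in enumerate(window)))


def specific_affinity(model: BindingModel, peptide: str) -> float:
    """Total specific-mode affinity: sum over offsets of exp(window energy)."""
    enc = encode_peptides([peptide])
    return float(np.exp(log_specific_affinity(model, enc)[0]))


def nonspecific_affinity(model: BindingModel, peptide: str) -> float:
    enc = encode_peptides([peptide])
    return float(np.exp(log_nonspecific_affinity(model, enc)[0]))


def predicted_enrichment(model: BindingModel, peptide: str, table_index: int) -> float:
    """kappa_c(s): activity-weighted sum of the two modes; strictly positive."""
    enc = encode_peptides([peptide])
    return float(np.exp(log_predicted_enrichment(model, enc, table_index)[0]))


# ---------------------------------------------------------------------------
# likelihood and regularization

def data_log_likelihood(model: BindingModel, tables: list[CountTable]) -> float:
    """Scaled binomial log-likelihood of input/bound splits over all tables.

    Each table c contributes (1/k_c) * sum_i [ k_I ln p_I + k_B ln p_B ]
    with p_I = eta_I / (eta_I + eta_B kappa) and p_B = 1 - p_I, where k_c is
    the table's total read count.  Always <= 0.
    """
    if len(tables) != model.n_tables:
        raise ValueError("one activity/depth pair required per table")
    total = 0.0
    for c, table in enumerate(tables):
        k_c = table.total_reads
        if k_c == 0:
            raise ValueError(f"table {table.round_label!r} has zero reads")
        eta_i, eta_b = model.depth_params[c]
        enc = encode_peptides(table.sequences)
        log_kappa = log_predicted_enrichment(model, enc, c)
        log_bound = np.log(eta_b) + log_kappa
        log_denom = np.logaddexp(np.log(eta_i), log_bound)
        total += (
            table.input_counts @ (np.log(eta_i) - log_denom)
            + table.bound_counts @ (log_bound - log_denom)
        ) / k_c
    return float(total)


@dataclass
class RegularizationConfig:
    """Penalty hyperparameters.

    ``l2_weight`` shrinks every free coefficient; ``barrier_bound`` sets the
    soft wall of the exponential barrier exp(b - bound) + exp(-b - bound)
    keeping coefficients in a bounded box; ``dirichlet_count`` is the
    pseudo-count of the Dirichlet prior on the per-table activity fractions,
    which resolves the scale freedom between the two binding modes.
    """

    l2_weight: float = 1e-6
    barrier_bound: float = 20.0
    dirichlet_count: float = 5.0


def free_coefficients(model: BindingModel) -> np.ndarray:
    """Flat vector of all penalized coefficients (frozen columns excluded)."""
    parts = [model.specific.coeffs[:, model.specific.free_column_mask()].ravel()]
    parts.append(model.nonspecific.matrix.coeffs.ravel())
    parts.append(model.nonspecific.bias(model.var_len))
    return np.concatenate(parts)


def regularization_penalty(model: BindingModel, config: RegularizationConfig) -> float:
    """L2 + exponential barrier on coefficients, Dirichlet on activity fractions."""
    beta = free_coefficients(model)
    pen = config.l2_weight * float(beta @ beta)
    pen += float(
        np.exp(beta - config.barrier_bound).sum() + np.exp(-beta - config.barrier_bound).sum()
    )
    for a_ns, a_s in model.activities:
        s = a_ns + a_s
        pen -= config.dirichlet_count * (np.log(a_ns / s) + np.log(a_s / s))
    return float(pen)


# ---------------------------------------------------------------------------
# serialization

def model_to_json(model: BindingModel, path=None) -> str:
    data = {
        "residue_order": AA_ALPHABET,
        "var_len": model.var_len,
        "flank_left": model.flank_left,
        "flank_right": model.flank_right,
        "flank_overlap": model.flank_overlap,
        "specific": {
            "width": model.specific.width,
            "center_index": model.specific.center_index,
            "constrained": model.specific.constrained,
            "coeffs": model.specific.coeffs.tolist(),
        },
        "nonspecific": {
            "width": model.nonspecific.matrix.width,
            "coeffs": model.nonspecific.matrix.coeffs.tolist(),
            "positional_bias": model.nonspecific.bias(model.var_len).tolist(),
        },
        "tables": [
            {
                "round_label": model.round_labels[c] if c < len(model.round_labels) else str(c),
                "alpha_ns": model.activities[c][0],
                "alpha_s": model.activities[c][1],
                "eta_i": model.depth_params[c][0],
                "eta_b": model.depth_params[c][1],
            }
            for c in range(model.n_tables)
        ],
    }
    text = json.dumps(data, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def model_from_json(source) -> BindingModel:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        data = json.loads(source)
    else:
        with open(source) as fh:
            data = json.load(fh)
    if data["residue_order"] != AA_ALPHABET:
        raise ValueError("unexpected residue order in model file")
    spec = EnergyMatrix(
        data["specific"]["width"],
        np.array(data["specific"]["coeffs"]),
        data["specific"]["center_index"],
        data["specific"]["constrained"],
    )
    ns = NonSpecificMode(
        EnergyMatrix(data["nonspecific"]["width"], np.array(data["nonspecific"]["coeffs"])),
        np.array(data["nonspecific"]["positional_bias"]),
    )
    return BindingModel(
        spec,
        ns,
        data["flank_left"],
        data["flank_right"],
        data["flank_overlap"],
        data["var_len"],
        [(t["alpha_ns"], t["alpha_s"]) for t in data["tables"]],
        [(t["eta_i"], t["eta_b"]) for t in data["tables"]],
        [t["round_label"] for t in data["tables"]],
    )
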