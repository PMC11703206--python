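"""Synthetic multi-round affinity-selection experiments with known truth.

Emulates repeated bead-based selection of a degenerate peptide-display
library: a pool of peptides is sequenced before selection (input column),
captured in proportion to its predicted enrichment kappa under a
ground-truth binding model (linear, non-saturating selection — the same
generative assumption the likelihood makes), sequenced again (bound
column), and the bound pool is carried noiselessly into the next round.

Every experiment returns both the per-round count tables and a
:class:`SimulationTruth` record, so parameter-recovery tests can compare
fitted free-energy matrices against the matrix that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .energy_model import (
    BindingModel,
    EnergyMatrix,
    NonSpecificMode,
    log_nonspecific_affinity,
    log_specific_affinity,
)
from .inference import apply_central_constraint
from .seqio import AA_ALPHABET, CountTable, LibraryDesign, encode_peptides

N_AA = len(AA_ALPHABET)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``nonspecific_fraction`` is the expected share of bound reads captured
    by the non-specific mode (0 disables it up to a numerical floor);
    ``phospho_efficiency`` is the fraction of tyrosine-containing library
    members competent for specific binding, emulating incomplete enzymatic
    phosphorylation of the displayed peptides.
    """

    design: LibraryDesign
    n_unique: int = 50_000
    rounds: int = 3
    reads_per_column: int = 200_000
    true_model: BindingModel | None = None
    nonspecific_fraction: float = 0.0
    phospho_efficiency: float = 1.0
    beta_sd: float = 1.0
    w_ns: int = 3
    seed: int = 0
    use_nns_frequencies: bool = False

    def __post_init__(self) -> None:
        if self.n_unique < 1 or self.rounds < 1 or self.reads_per_column < 1:
            raise ValueError("n_unique, rounds and reads_per_column must be >= 1")
        if not 0.0 <= self.nonspecific_fraction < 1.0:
            raise ValueError("nonspecific_fraction must be in [0, 1)")
        if not 0.0 < self.phospho_efficiency <= 1.0:
            raise ValueError("phospho_efficiency must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth retained alongside simulated count tables."""

    sequences: list[str]
    true_model: BindingModel
    kappas: np.ndarray  # effective per-sequence enrichment (after suppression)
    pool_frequencies: list[np.ndarray] = field(default_factory=list)  # per round
    competent: np.ndarray | None = None


def nns_residue_frequencies() -> np.ndarray:
    """Amino-acid frequencies of the NNS degenerate codon scheme (stops excluded)."""
    counts = np.zeros(N_AA)
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "GC":
                aa = str(Seq(b1 + b2 + b3).translate())
                if aa in AA_ALPHABET:
                    counts[AA_ALPHABET.index(aa)] += 1
    return counts / counts.sum()


def draw_library(
    design: LibraryDesign,
    n_unique: int,
    seed: int,
    use_nns_frequencies: bool = False,
) -> list[str]:
    """Sample distinct peptides uniformly over the design's sequence space.

    Fixed positions are respected; residue frequencies are uniform unless
    NNS codon-usage weighting is requested.
    """
    if n_unique < 1:
        raise ValueError("n_unique must be >= 1")
    rng = np.random.default_rng(seed)
    L = design.var_len_aa
    probs = nns_residue_frequencies() if use_nns_frequencies else np.full(N_AA, 1.0 / N_AA)
    fixed = {p: AA_ALPHABET.index(r) for p, r in design.fixed_positions.items()}
    seen: dict[str, None] = {}
    alphabet = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    while len(seen) < n_unique:
        batch = max(n_unique - len(seen), 1024)
        draws = rng.choice(N_AA, size=(batch, L), p=probs)
        for p, r in fixed.items():
            draws[:, p] = r
        chars = alphabet[draws]
        for row in chars:
            seen.setdefault(row.tobytes().decode("ascii"), None)
            if len(seen) == n_unique:
                break
    return list(seen)


def make_true_model(
    design: LibraryDesign,
    seed: int,
    beta_sd: float = 1.0,
    w_ns: int = 3,
    n_tables: int = 1,
    nonspecific_fraction: float = 0.0,
    library: list[str] | None = None,
) -> BindingModel:
    """Build a ground-truth model with random non-central coefficients.

    The specific matrix has the central-tyrosine constraint and free
    coefficients drawn N(0, beta_sd^2).  The non-specific activity is
    calibrated on ``library`` (or a fresh draw) so that the requested
    fraction of bound reads from a uniform pool is non-specific capture.
    """
    rng = np.random.default_rng(seed)
    L = design.var_len_aa
    spec = EnergyMatrix(L, rng.normal(0.0, beta_sd, (N_AA, L)))
    spec = apply_central_constraint(spec, "Y")
    ns = NonSpecificMode(EnergyMatrix(w_ns), np.zeros(L - w_ns + 1))
    model = BindingModel(
        spec, ns,
        design.left_flank_aa, design.right_flank_aa, 5, L,
        [(1.0, 1.0)], [(1.0, 1.0)],
    )
    if library is None:
        library = draw_library(design, min(5000, 20 ** L), seed + 1)
    enc = encode_peptides(library)
    mean_s = float(np.exp(log_specific_affinity(model, enc)).mean())
    mean_ns = float(np.exp(log_nonspecific_affinity(model, enc)).mean())
    f = nonspecific_fraction
    alpha_ns = max(f / (1.0 - f) * mean_s / mean_ns, 1e-12) if f < 1 else 1.0
    model.activities = [(alpha_ns, 1.0)] * n_tables
    model.depth_params = [(1.0, 1.0)] * n_tables
    return model


def effective_kappas(
    model: BindingModel,
    sequences: list[str],
    table_index: int = 0,
    competent: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sequence enrichment, with the specific term zeroed for
    phosphorylation-incompetent members."""
    enc = encode_peptides(sequences)
    a_ns, a_s = model.activities[table_index]
    ns = a_ns * np.exp(log_nonspecific_affinity(model, enc))
    s = a_s * np.exp(log_specific_affinity(model, enc))
    if competent is not None:
        s = s * competent
    return ns + s


def run_selection_round(
    sequences: list[str],
    pool_freqs: np.ndarray,
    kappas: np.ndarray,
    reads_per_column: int,
    seed: int,
    round_label: str = "r1",
) -> tuple[CountTable, np.ndarray]:
    """One round of linear selection with multinomial sequencing noise.

    Bound frequencies are proportional to pool frequency times kappa; both
    columns are sampled multinomially at the requested depth.  The bound
    frequency vector doubles as the next round's pool (noiseless
    re-amplification).  Rows unobserved in both columns are dropped from
    the emitted table, as in real sequencing.
    """
    pool_freqs = np.asarray(pool_freqs, dtype=float)
    if pool_freqs.size == 0:
        raise ValueError("empty pool")
    if not np.isclose(pool_freqs.sum(), 1.0):
        raise ValueError("pool frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    bound_freqs = pool_freqs * kappas
    bound_freqs = bound_freqs / bound_freqs.sum()
    inp = rng.multinomial(reads_per_column, pool_freqs)
    bnd = rng.multinomial(reads_per_column, bound_freqs)
    table = CountTable(round_label, list(sequences), inp, bnd).drop_empty_rows()
    return table, bound_freqs


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[CountTable], SimulationTruth]:
    """Chain selection rounds into a full synthetic experiment."""
    rng = np.random.default_rng(config.seed)
    lib_seed, comp_seed = rng.integers(0, 2**31 - 1, size=2)
    sequences = draw_library(
        config.design, config.n_unique, int(lib_seed), config.use_nns_frequencies
    )
    model = config.true_model
    if model is None:
        model = make_true_model(
            config.design,
            config.seed,
            beta_sd=config.beta_sd,
            w_ns=config.w_ns,
            n_tables=config.rounds,
            nonspecific_fraction=config.nonspecific_fraction,
            library=sequences,
        )
    elif len(model.activities) < config.rounds:
        model = model.copy()
        model.activities = [model.activities[0]] * config.rounds
        model.depth_params = [model.depth_params[0]] * config.rounds

    competent = None
    if config.phospho_efficiency < 1.0:
        comp_rng = np.random.default_rng(int(comp_seed))
        has_tyr = np.array([("Y" in s) for s in sequences])
        competent = np.where(
            has_tyr, comp_rng.random(len(sequences)) < config.phospho_efficiency, True
        ).astype(float)

    kappas = effective_kappas(model, sequences, 0, competent)
    pool = np.full(len(sequences), 1.0 / len(sequences))
    tables: list[CountTable] = []
    truth = SimulationTruth(sequences, model, kappas, [pool], competent)
    for r in range(config.rounds):
        round_seed = int(rng.integers(0, 2**31 - 1))
        table, pool = run_selection_round(
            sequences, pool, kappas, config.reads_per_column, round_seed, f"r{r + 1}"
        )
        tables.append(table)
        truth.pool_frequencies.append(pool)
    return tables, truth
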