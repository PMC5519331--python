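"""Inter-protein coevolution by direct coupling analysis over stochastically
paralog-matched paired alignments.

The interaction partners of two protein families cannot always be paired by
genomic context; organisms carry variable numbers of paralogs of each family.
The pipeline therefore builds an ensemble of randomly matched paired
alignments (one partner per sequence, per organism), fits a 21-state Potts
model to each by asymmetric pseudo-likelihood maximization, scores column
pairs by the APC-corrected Frobenius norm of the coupling blocks, and ranks
inter-protein pairs by the frequency with which their renormalized score
clears a threshold across matching realizations.  Predicted contacts whose
residues are buried (solvent-accessible surface area below a threshold) are
filtered out against a full-atom structure.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .structures import (
    AA_ALPHABET,
    ContactPrediction,
    FamilyMSA,
    PairedMSA,
)

__all__ = [
    "PottsModel",
    "ScoreMatrix",
    "MatchingRealization",
    "sequence_weights",
    "fit_plm",
    "frobenius_scores",
    "apc_correct",
    "normalize_scores",
    "random_match",
    "run_matching_realization",
    "selection_frequencies",
    "empirical_interprotein_score",
    "sasa_filter",
    "compute_sasa",
    "AVERAGE_RESIDUE_SASA",
]

_Q = len(AA_ALPHABET)   # 21 states: gap + 20 amino acids


# ---------------------------------------------------------------------------
# Sequence weighting
# ---------------------------------------------------------------------------

def sequence_weights(msa: PairedMSA | FamilyMSA,
                     identity_threshold: float = 0.9) -> tuple[np.ndarray, float]:
    """Down-weight redundant rows: w_i = 1/|{j : identity(i, j) ≥ t}|.

    Identity is the fraction of equal symbols over all columns (gaps
    included).  The count includes the row itself, so weights lie in (0, 1].
    Returns ``(weights, Neff)`` and stores the weights on the MSA.
    """
    seqs = msa.sequences
    m, n = seqs.shape
    if m == 0:
        raise ValueError("empty MSA")
    # one-hot matmul counts matches for all row pairs at once
    x = np.zeros((m, n * _Q), dtype=np.float32)
    x[np.arange(m)[:, None].repeat(n, 1).ravel(),
      (np.arange(n) * _Q + seqs).ravel()] = 1.0
    matches = x @ x.T
    neighbors = (matches / n >= identity_threshold - 1e-12).sum(axis=1)
    weights = 1.0 / neighbors
    if isinstance(msa, PairedMSA):
        msa.weights = weights
    return weights, float(weights.sum())


# ---------------------------------------------------------------------------
# Potts model by asymmetric pseudo-likelihood
# ---------------------------------------------------------------------------

@dataclass
class PottsModel:
    """Fitted Potts parameters: couplings J[i, j, a, b] and fields h[i, a].

    ``J`` is symmetrized (J[i, j, a, b] == J[j, i, b, a]); the diagonal
    blocks are zero.
    """

    J: np.ndarray                    # (N, N, q, q)
    h: np.ndarray                    # (N, q)
    lambda_J: float
    lambda_h: float
    converged: bool = True
    grad_norms: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self.h.shape[0]


def fit_plm(msa: PairedMSA, lambda_J: float = 0.01, lambda_h: float = 0.01,
            gtol: float = 1e-5, maxiter: int = 2000) -> PottsModel:
    """Fit the Potts model by asymmetric pseudo-likelihood maximization.

    Each column's conditional distribution given the rest of the row is a
    multinomial logistic model; the weighted negative log-likelihood (weights
    from :func:`sequence_weights`, normalized by their sum) plus L2 penalties
    λ_h·Σh² and λ_J·ΣJ² is minimized per column with L-BFGS, and the
    per-column coupling estimates are symmetrized
    J_ij(a, b) ← (J_ij(a, b) + J_ji(b, a))/2.
    """
    seqs = msa.sequences
    m, n = seqs.shape
    if n < 2:
        raise ValueError("alignment width must be at least 2")
    if msa.weights is None:
        sequence_weights(msa)
    w = np.asarray(msa.weights, dtype=np.float64)
    w_sum = w.sum()
    if w_sum <= 1.0 and m > 1:
        warnings.warn("Neff ≤ 1; couplings will be regularization-dominated")

    # global one-hot design matrix, reused for every column
    x = np.zeros((m, n * _Q), dtype=np.float64)
    x[np.arange(m)[:, None].repeat(n, 1).ravel(),
      (np.arange(n) * _Q + seqs).ravel()] = 1.0

    j_asym = np.zeros((n, n, _Q, _Q))
    h = np.zeros((n, _Q))
    grad_norms = np.zeros(n)
    converged = True

    for i in range(n):
        cols = np.ones(n * _Q, dtype=bool)
        cols[i * _Q:(i + 1) * _Q] = False
        f = x[:, cols]                        # (m, (n-1)q)
        y = seqs[:, i]
        y_onehot = np.zeros((m, _Q))
        y_onehot[np.arange(m), y] = 1.0
        n_feat = f.shape[1]

        def objective(theta):
            hw = theta[:_Q]
            jw = theta[_Q:].reshape(n_feat, _Q)
            logits = hw[None, :] + f @ jw
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            z = expl.sum(axis=1)
            p = expl / z[:, None]
            ll = (logits[np.arange(m), y] - np.log(z)) @ w
            resid = (p - y_onehot) * w[:, None]
            grad_h = resid.sum(axis=0) / w_sum + 2.0 * lambda_h * hw
            grad_j = f.T @ resid / w_sum + 2.0 * lambda_J * jw
            val = (-ll / w_sum
                   + lambda_h * np.sum(hw ** 2) + lambda_J * np.sum(jw ** 2))
            return val, np.concatenate([grad_h, grad_j.ravel()])

        res = minimize(objective, np.zeros(_Q + n_feat * _Q),
                       method="L-BFGS-B", jac=True,
                       options={"maxiter": maxiter, "gtol": gtol,
                                "ftol": 1e-12})
        grad_norms[i] = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norms[i] > 10 * gtol:
            raise RuntimeError(
                f"pseudo-likelihood optimization failed for column {i}: "
                f"{res.message} (|grad|_inf = {grad_norms[i]:.3g})"
            )
        h[i] = res.x[:_Q]
        jw = res.x[_Q:].reshape(n_feat, _Q)
        others = [j for j in range(n) if j != i]
        blocks = jw.reshape(n - 1, _Q, _Q)    # [j, b, a]: feature (j, b) -> class a
        for k, j in enumerate(others):
            j_asym[i, j] = blocks[k].T        # [a, b]

    j_sym = 0.5 * (j_asym + np.transpose(j_asym, (1, 0, 3, 2)))
    return PottsModel(J=j_sym, h=h, lambda_J=lambda_J, lambda_h=lambda_h,
                      converged=converged, grad_norms=grad_norms)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreMatrix:
    """Raw, APC-corrected and renormalized coupling scores for one fit."""

    s_raw: np.ndarray                # (N, N) symmetric
    s_apc: np.ndarray                # (N, N)
    s_tilde: np.ndarray | None       # (N_A, N_B) inter-segment only
    boundary: int
    n: int
    neff: float


def zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    """Shift a q×q coupling block to the zero-sum gauge."""
    return (block
            - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True)
            + block.mean())


def frobenius_scores(model: PottsModel) -> np.ndarray:
    """Frobenius norm of each zero-sum-gauged coupling block.

    The norm runs over the full 21×21 block (gap state included); the
    diagonal is zero and the matrix is symmetric and non-negative.
    """
    j = model.J
    gauged = (j
              - j.mean(axis=2, keepdims=True)
              - j.mean(axis=3, keepdims=True)
              + j.mean(axis=(2, 3), keepdims=True))
    s = np.sqrt(np.sum(gauged ** 2, axis=(2, 3)))
    np.fill_diagonal(s, 0.0)
    return s


def apc_correct(s_raw: np.ndarray, boundary: int) -> np.ndarray:
    """Two-segment average-product correction.

    Positional mutation-rate bias differs between the two protein families,
    so the APC means are taken over each segment pair independently: for an
    inter-segment pair (i in A, j in B), the row mean runs over i's couplings
    to segment B, the column mean over j's couplings to segment A, and the
    grand mean over the inter-segment block; intra-segment blocks use the
    standard APC restricted to the segment (diagonal excluded).
    """
    s = np.asarray(s_raw, dtype=float)
    n = s.shape[0]
    if s.shape != (n, n) or not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("s_raw must be square and symmetric")
    if not (0 < boundary < n):
        raise ValueError("boundary out of range")
    out = np.zeros_like(s)
    a = slice(0, boundary)
    b = slice(boundary, n)

    def _intra(block):
        k = block.shape[0]
        if k < 2:
            return np.zeros_like(block)
        row = block.sum(axis=1) / (k - 1)          # diagonal entries are zero
        grand = block.sum() / (k * (k - 1))
        if grand == 0:
            if np.allclose(block, 0.0):
                return np.zeros_like(block)        # nothing to correct
            raise ValueError("zero grand mean in intra-segment APC")
        corr = block - np.outer(row, row) / grand
        np.fill_diagonal(corr, 0.0)
        return corr

    def _inter(block):
        if block.shape == (1, 1):
            return np.zeros_like(block)           # S − S·S/S is identically 0
        row = block.mean(axis=1)
        col = block.mean(axis=0)
        grand = block.mean()
        if grand == 0:
            if np.allclose(block, 0.0):
                return np.zeros_like(block)
            raise ValueError("zero grand mean in inter-segment APC")
        return block - np.outer(row, col) / grand

    out[a, a] = _intra(s[a, a])
    out[b, b] = _intra(s[b, b])
    inter = _inter(s[a, b])
    out[a, b] = inter
    out[b, a] = inter.T
    return out


def normalize_scores(s: np.ndarray, boundary: int, n: int, neff: float,
                     variant: str = "multiply") -> np.ndarray:
    """Renormalized inter-protein scores S̃ = S/|min S_inter| · (1 + N/Neff).

    The minimum is restricted to the inter-segment block.  ``variant`` can be
    ``"divide"`` to apply the alternative 1/(1 + N/Neff) convention; the
    multiplicative form is the default.  The renormalization is monotone, so
    the relative ranking of inter-protein pairs is unchanged.  Returned as an
    (N_A, N_B) matrix over inter-segment pairs only.
    """
    inter = np.asarray(s, dtype=float)[:boundary, boundary:]
    if inter.size == 0:
        raise ValueError("empty inter-segment block")
    mn = inter.min()
    if mn == 0:
        raise ValueError("minimum inter-segment score is zero; cannot normalize")
    factor = 1.0 + n / neff
    if variant == "multiply":
        return inter / abs(mn) * factor
    if variant == "divide":
        return inter / abs(mn) / factor
    raise ValueError(f"unknown variant {variant!r}")


def empirical_interprotein_score(s: np.ndarray, boundary: int) -> float:
    """Mean of the four strongest inter-segment APC scores."""
    inter = np.asarray(s, dtype=float)[:boundary, boundary:].ravel()
    if inter.size < 4:
        raise ValueError("need at least 4 inter-segment pairs")
    return float(np.mean(np.sort(inter)[-4:]))


# ---------------------------------------------------------------------------
# Random paralog matching
# ---------------------------------------------------------------------------

def random_match(family_a: FamilyMSA, family_b: FamilyMSA,
                 seed: int | np.random.Generator = 0) -> PairedMSA:
    """One stochastic realization of the paralog-matching problem.

    Within each organism present in both families, sequences are paired
    uniformly at random without replacement until the smaller family is
    exhausted; leftovers stay unpaired.  Organisms with exactly one sequence
    in each family are therefore paired deterministically and appear in every
    realization.  Each source sequence enters at most one row.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    orgs_a: dict = {}
    for i, o in enumerate(family_a.organism_ids):
        orgs_a.setdefault(o, []).append(i)
    orgs_b: dict = {}
    for i, o in enumerate(family_b.organism_ids):
        orgs_b.setdefault(o, []).append(i)
    shared = [o for o in orgs_a if o in orgs_b]
    if not shared:
        raise ValueError("families share no organisms")

    rows, orgs, la, lb = [], [], [], []
    for o in sorted(shared, key=str):
        ia = np.array(orgs_a[o])
        ib = np.array(orgs_b[o])
        rng.shuffle(ia)
        rng.shuffle(ib)
        k = min(len(ia), len(ib))
        for t in range(k):
            rows.append(np.concatenate([family_a.sequences[ia[t]],
                                        family_b.sequences[ib[t]]]))
            orgs.append(o)
            la.append(family_a.labels[ia[t]])
            lb.append(family_b.labels[ib[t]])
    return PairedMSA(
        sequences=np.array(rows, dtype=np.int8),
        boundary=family_a.width,
        organism_ids=np.array(orgs),
        labels_a=np.array(la),
        labels_b=np.array(lb),
    )


@dataclass
class MatchingRealization:
    """DCA results for one random-matching realization."""

    paired_msa: PairedMSA
    seed: int
    scores: ScoreMatrix
    selected_pairs: list[tuple[int, int]]     # (col_A, col_B within segment B)
    empirical_score: float


def run_matching_realization(
    family_a: FamilyMSA,
    family_b: FamilyMSA,
    seed: int,
    score_threshold: float = 0.8,
    lambda_J: float = 0.01,
    lambda_h: float = 0.01,
    identity_threshold: float = 0.9,
    normalize_variant: str = "multiply",
) -> MatchingRealization:
    """Match → weight → fit → score → select, for one realization seed."""
    paired = random_match(family_a, family_b, seed)
    _, neff = sequence_weights(paired, identity_threshold)
    model = fit_plm(paired, lambda_J=lambda_J, lambda_h=lambda_h)
    s_raw = frobenius_scores(model)
    s_apc = apc_correct(s_raw, paired.boundary)
    s_tilde = normalize_scores(s_apc, paired.boundary, paired.width, neff,
                               variant=normalize_variant)
    sel = [(int(i), int(j)) for i, j in zip(*np.where(s_tilde > score_threshold))]
    scores = ScoreMatrix(s_raw=s_raw, s_apc=s_apc, s_tilde=s_tilde,
                         boundary=paired.boundary, n=paired.width, neff=neff)
    return MatchingRealization(
        paired_msa=paired,
        seed=seed,
        scores=scores,
        selected_pairs=sel,
        empirical_score=empirical_interprotein_score(s_apc, paired.boundary),
    )


def selection_frequencies(
    family_a: FamilyMSA,
    family_b: FamilyMSA,
    n_realizations: int = 1000,
    score_threshold: float = 0.8,
    seed: int = 0,
    residue_map_a: dict[int, int] | None = None,
    residue_map_b: dict[int, int] | None = None,
    return_realizations: bool = False,
    **fit_kwargs,
):
    """Selection frequency of every inter-protein pair over the matching
    ensemble.

    One master seed spawns independent per-realization seeds.  For each
    realization the full pipeline runs (match, weight, pseudo-likelihood fit,
    Frobenius + APC + renormalization) and inter-segment pairs with
    S̃ > ``score_threshold`` are recorded; a pair's frequency is the fraction
    of realizations selecting it.  Returns predictions sorted by descending
    frequency (column-index tie-break); with ``return_realizations`` also the
    per-realization records.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_realizations)
    child_seeds = (child_seeds % (2 ** 31)).astype(np.int64)
    counts: dict[tuple[int, int], int] = {}
    realizations = []
    for s in child_seeds:
        real = run_matching_realization(
            family_a, family_b, int(s), score_threshold=score_threshold,
            **fit_kwargs)
        for pair in real.selected_pairs:
            counts[pair] = counts.get(pair, 0) + 1
        if return_realizations:
            realizations.append(real)
        else:
            realizations.append(real.empirical_score)

    preds = []
    for (ca, cb), c in counts.items():
        preds.append(ContactPrediction(
            column_a=ca,
            column_b=cb,
            residue_a=residue_map_a.get(ca) if residue_map_a else None,
            residue_b=residue_map_b.get(cb) if residue_map_b else None,
            frequency=c / n_realizations,
        ))
    preds.sort(key=lambda p: (-p.frequency, p.column_a, p.column_b))
    if return_realizations:
        return preds, realizations
    return preds


# ---------------------------------------------------------------------------
# SASA computation and buried-contact filtering
# ---------------------------------------------------------------------------

#: Average per-residue solvent-accessible surface area (Å²) used to normalize
#: raw SASA values; standard tripeptide-context averages.  Configurable.
AVERAGE_RESIDUE_SASA = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def compute_sasa(
    pdb_text: str,
    chain: str | None = None,
    residues: list[int] | None = None,
    reference_table: dict[str, float] | None = None,
    point_number: int = 500,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-residue SASA (Å²) of a full-atom structure by rolling-probe
    (Shrake–Rupley) integration, plus values normalized to the average SASA
    of each amino-acid type.

    Requires full-atom coordinates (a Cα trace is insufficient).  Returns
    ``(sasa, normalized)`` keyed by author residue number.
    """
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    if reference_table is None:
        reference_table = AVERAGE_RESIDUE_SASA
    pf = PDBFile.read(io.StringIO(pdb_text))
    arr = pf.get_structure(model=1)
    arr = arr[bst.filter_amino_acids(arr)]
    arr = arr[arr.element != "H"]
    if chain is not None:
        arr = arr[arr.chain_id == chain]
    if arr.array_length() == 0:
        raise ValueError("no amino-acid atoms found")
    # a bare Cα trace cannot support a rolling-probe calculation
    res_ids_all = np.unique(arr.res_id)
    if np.mean(np.isin(arr.atom_name, ["CA"])) > 0.9:
        raise ValueError("structure appears to be Cα-only; full atoms required")
    atom_sasa = bst.sasa(arr, vdw_radii="ProtOr", point_number=point_number)
    n_nan = int(np.isnan(atom_sasa).sum())
    if n_nan:
        warnings.warn(f"{n_nan} atoms had no radius assigned and were skipped")
    sasa: dict[int, float] = {}
    norm: dict[int, float] = {}
    wanted = set(residues) if residues is not None else None
    for rid in res_ids_all:
        if wanted is not None and int(rid) not in wanted:
            continue
        sel = arr.res_id == rid
        total = float(np.nansum(atom_sasa[sel]))
        sasa[int(rid)] = total
        res3 = arr.res_name[sel][0]
        one = _THREE_TO_ONE.get(res3)
        ref = reference_table.get(one) if one else None
        norm[int(rid)] = total / ref if ref else math.nan
    if wanted is not None:
        missing = wanted - set(sasa)
        if missing:
            raise KeyError(f"residues missing from structure: {sorted(missing)}")
    return sasa, norm


def sasa_filter(
    predictions: list[ContactPrediction],
    sasa_a: dict[int, float],
    sasa_b: dict[int, float],
    burial_threshold: float = 1.0,
    mode: str = "stop",
) -> list[ContactPrediction]:
    """Flag predictions against per-residue SASA of the two structures.

    ``mode="stop"``: walk the predictions in descending frequency and retain
    them until the first pair containing a buried residue (SASA below
    ``burial_threshold`` Å²); that pair and everything ranked below it is
    flagged not-retained.  ``mode="discard"``: drop only the pairs that
    themselves contain a buried residue, keeping the rest.

    Residue keys are the predictions' mapped residue ids (falling back to
    column indices).  A predicted residue absent from the SASA map is an
    error naming it.
    """
    if mode not in ("stop", "discard"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    stopped = False
    ordered = sorted(predictions,
                     key=lambda p: (-p.frequency,
                                    p.residue_a if p.residue_a is not None else p.column_a,
                                    p.residue_b if p.residue_b is not None else p.column_b))
    for p in ordered:
        ra = p.residue_a if p.residue_a is not None else p.column_a
        rb = p.residue_b if p.residue_b is not None else p.column_b
        if ra not in sasa_a:
            raise KeyError(f"residue {ra} missing from structure A SASA map")
        if rb not in sasa_b:
            raise KeyError(f"residue {rb} missing from structure B SASA map")
        buried = sasa_a[ra] < burial_threshold or sasa_b[rb] < burial_threshold
        if mode == "stop":
            if buried:
                stopped = True
            retained = not stopped
        else:
            retained = not buried
        out.append(ContactPrediction(
            column_a=p.column_a, column_b=p.column_b,
            residue_a=p.residue_a, residue_b=p.residue_b,
            frequency=p.frequency,
            sasa_a=sasa_a[ra], sasa_b=sasa_b[rb],
            retained=retained,
        ))
    return out
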