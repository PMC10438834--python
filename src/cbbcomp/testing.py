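"""Significance calls from posterior draws.

A *null probability* per group is the posterior probability that the effect
(a contrast of regression coefficients, on the CLR scale for composition or
the log-concentration scale for variability) is NOT larger in magnitude
than a fold-change threshold (0.2 by default), resolved one-sided in the
direction of the posterior mean.  Null probabilities are converted to a
local false-discovery rate by sorting ascending and taking the running mean
(Stephens-style cumulative average).

Result tables are plain DataFrames with one row per (group, coefficient)
and columns: effect_mean, ci_low, ci_high, prob_null, fdr, significant,
n_outliers, rhat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "effect_probability",
    "fdr_from_probs",
    "test_composition",
    "test_variability",
]

# result tables are pandas DataFrames with this column contract
TestResultTable = pd.DataFrame


def effect_probability(draws, threshold=0.2):
    """Posterior probability of no effect beyond ``threshold``.

    One-sided in the direction of the posterior mean: P(null) =
    1 - P(draw > +t) when the mean is positive, 1 - P(draw < -t) when
    negative.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be nonempty")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if draws.mean() >= 0:
        p_effect = float(np.mean(draws > threshold))
    else:
        p_effect = float(np.mean(draws < -threshold))
    return 1.0 - p_effect


def fdr_from_probs(prob_null):
    """Running-mean false-discovery rate from sorted null probabilities.

    Sort ascending, take the cumulative average, and map the values back
    to the input order.
    """
    p = np.asarray(prob_null, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("null probabilities must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    running = np.cumsum(p[order]) / np.arange(1, p.size + 1)
    fdr = np.empty_like(running)
    fdr[order] = running
    return fdr


def _resolve_contrast(contrast, design, what):
    """Turn a coefficient name or vector into a validated contrast vector."""
    if isinstance(contrast, str):
        vec = np.zeros(design.n_coef)
        vec[design.coef_index(contrast)] = 1.0
        return vec
    vec = np.asarray(contrast, dtype=float)
    if vec.shape != (design.n_coef,):
        raise ValueError(f"{what} contrast must have length "
                         f"{design.n_coef} (coefficients "
                         f"{design.row_names})")
    if np.all(vec == 0):
        raise ValueError(f"{what} contrast must not be all zeros")
    if abs(np.max(np.abs(vec)) - 1.0) > 1e-8:
        raise ValueError(
            f"{what} contrast must be normalized to max |entry| = 1: the "
            "fold-change threshold applies on the per-unit effect scale, "
            "so c and 2c are different tests")
    return vec


def _contrast_label(vec, design):
    terms = [f"{w:+g}*{design.row_names[i]}" if w not in (1.0,) else
             design.row_names[i]
             for i, w in enumerate(vec) if w != 0]
    return " ".join(terms)


def _default_contrasts(design):
    """One identity contrast per non-intercept coefficient."""
    names = [n for i, n in enumerate(design.row_names)
             if i != design.intercept_row]
    if not names:
        names = list(design.row_names)
    return names


def _group_rhat(post, prefix):
    model = post.model
    out = {}
    for g, gname in enumerate(model.table.group_ids):
        vals = [v for k, v in post.rhat.items()
                if k.startswith(f"{prefix}[{gname},")
                or k.startswith(f"{prefix}_z[{gname},")]
        out[gname] = float(np.nanmax(vals)) if vals else np.nan
    return out


def _finalize(rows, fdr_threshold):
    frame = pd.DataFrame(rows)
    frame["fdr"] = fdr_from_probs(frame["prob_null"].to_numpy())
    frame["significant"] = frame["fdr"] < fdr_threshold
    cols = ["group", "coefficient", "kind", "effect_mean", "ci_low",
            "ci_high", "prob_null", "fdr", "significant", "n_outliers",
            "rhat"]
    return frame[cols]


def test_composition(post, contrast=None, threshold=0.2, fdr_threshold=0.05,
                     level=0.95):
    """Test composition effects per group for one or more contrasts.

    ``contrast`` may be a coefficient name, a length-C vector in the
    coefficient basis of the zero-sum parameterization, or None to test
    every non-intercept coefficient.  The FDR is computed across all rows
    of the resulting table.
    """
    model = post.model
    if contrast is None:
        contrasts = _default_contrasts(model.design)
    else:
        contrasts = [contrast]
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    n_out = _outlier_counts(post)
    rhat = _group_rhat(post, "gamma")
    rows = []
    for con in contrasts:
        vec = _resolve_contrast(con, model.design, "composition")
        label = con if isinstance(con, str) else _contrast_label(
            vec, model.design)
        effects = np.einsum("dgc,c->dg", post.gamma, vec)
        for g, gname in enumerate(model.table.group_ids):
            d = effects[:, g]
            rows.append({
                "group": gname, "coefficient": label, "kind": "composition",
                "effect_mean": float(d.mean()),
                "ci_low": float(np.quantile(d, lo_q)),
                "ci_high": float(np.quantile(d, hi_q)),
                "prob_null": effect_probability(d, threshold),
                "n_outliers": n_out.get(gname, 0),
                "rhat": rhat[gname],
            })
    return _finalize(rows, fdr_threshold)


def test_variability(post, contrast=None, threshold=0.2, fdr_threshold=0.05,
                     level=0.95):
    """Test adjusted differential variability per group.

    Per draw the variability contrast of omega is reduced by lambda1 times
    the matching composition contrast of the means, removing the leakage of
    differential composition through the mean-variability line.  Matching
    is by coefficient name between the variability and composition designs.
    Signs are reported on the variability scale (-omega): a positive effect
    means *more* variable.
    """
    model = post.model
    if contrast is None:
        contrasts = _default_contrasts(model.vdesign)
    else:
        contrasts = [contrast]
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    n_out = _outlier_counts(post)
    rhat = _group_rhat(post, "omega")
    lam1 = (post.lambda1 if post.lambda1 is not None
            else np.zeros(post.n_draws))
    rows = []
    for con in contrasts:
        vec = _resolve_contrast(con, model.vdesign, "variability")
        # matching composition contrast, by coefficient name
        comp_vec = np.zeros(model.C)
        for i, w in enumerate(vec):
            if w == 0:
                continue
            name = model.vdesign.row_names[i]
            try:
                comp_vec[model.design.coef_index(name)] = w
            except KeyError:
                raise ValueError(
                    f"variability contrast uses coefficient {name!r} absent "
                    "from the composition design; the composition-leakage "
                    "adjustment needs the matching mean contrast") from None
        label = con if isinstance(con, str) else _contrast_label(
            vec, model.vdesign)
        omega_eff = np.einsum("dgv,v->dg", post.omega, vec)
        mu_eff = np.einsum("dgc,c->dg", post.gamma, comp_vec)
        adjusted = omega_eff - lam1[:, None] * mu_eff
        effects = -adjusted  # report on the variability (-omega) scale
        for g, gname in enumerate(model.table.group_ids):
            d = effects[:, g]
            rows.append({
                "group": gname, "coefficient": label, "kind": "variability",
                "effect_mean": float(d.mean()),
                "ci_low": float(np.quantile(d, lo_q)),
                "ci_high": float(np.quantile(d, hi_q)),
                "prob_null": effect_probability(d, threshold),
                "n_outliers": n_out.get(gname, 0),
                "rhat": rhat[gname],
            })
    return _finalize(rows, fdr_threshold)


def _outlier_counts(post):
    if post.outlier_mask is None:
        return {}
    model = post.model
    counts = np.asarray(post.outlier_mask).sum(axis=1)
    return {g: int(c) for g, c in zip(model.table.group_ids, counts)}
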