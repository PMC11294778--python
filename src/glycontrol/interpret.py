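"""Attention-based interpretability.

The model's explanation of a prediction has two parts: the self-attention
maps describe which past weeks the encoder relates to one another, and the
cross-attention vector describes how much each observed week contributes to
the classification.  Per-instance records can be averaged within
*concordance groups* — subsets defined by the agreement pattern between the
model, a comparator classifier (a gradient-boosted tree by default), and
the true outcome — to ask where the two models look when they agree and
when they disagree.

Reductions (the plotted curves do not define one): heads are averaged
within a layer, then layers are averaged; the per-week self-attention
salience is the mean attention a key week receives over observed query
rows.  The week axis is reported as weeks before the reference date
(0 = the reference week).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AttentionRecord, HbA1cTransformer

__all__ = [
    "GROUP_IDS",
    "AttentionProfile",
    "extract_attention",
    "assign_groups",
    "group_attention_profile",
    "profile_to_frame",
]

#: (model decision, comparator decision, true label) -> group
GROUP_IDS = ("TP_both", "TN_both", "TP_model_FN_comparator", "FN_model_TP_comparator")

_GROUP_RULES = {
    "TP_both": (1, 1, 1),
    "TN_both": (0, 0, 0),
    "TP_model_FN_comparator": (1, 0, 1),
    "FN_model_TP_comparator": (0, 1, 1),
}


@dataclass
class AttentionProfile:
    """Observed-only per-week means over a group of instances."""

    group_id: str
    weeks_before_reference: np.ndarray
    mean_hba1c: np.ndarray
    mean_self_attention: np.ndarray
    mean_cross_attention: np.ndarray
    n_observed: np.ndarray
    n_instances: int


def extract_attention(model: HbA1cTransformer, x) -> AttentionRecord:
    """Attention record for a single instance (a length-W NaN-masked row)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return model.attention_records(x)[0]


def assign_groups(model_decisions, comparator_decisions, labels) -> dict[str, np.ndarray]:
    """Partition instances by (model, comparator, truth) agreement.

    Returns a dict mapping each group id to the member indices; instances
    matching none of the four patterns (e.g. false positives) stay
    unassigned.
    """
    m = np.asarray(model_decisions).astype(int).ravel()
    c = np.asarray(comparator_decisions).astype(int).ravel()
    y = np.asarray(labels).astype(int).ravel()
    if not (len(m) == len(c) == len(y)):
        raise ValueError("decision and label vectors must have equal length")
    return {
        gid: np.flatnonzero((m == dm) & (c == dc) & (y == dy))
        for gid, (dm, dc, dy) in _GROUP_RULES.items()
    }


def group_attention_profile(
    records: list[AttentionRecord], X, members, group_id: str = ""
) -> AttentionProfile:
    """Average HbA1c level, self-attention salience, and cross-attention
    weight per week over a group, using only instances where the week is
    observed."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError(f"empty group {group_id!r}: no instances to average")
    X = np.asarray(X, dtype=float)
    w = X.shape[1]
    obs = np.stack([records[i].observed_mask for i in members])
    vals = np.nan_to_num(X[members], nan=0.0)
    self_sal = np.stack([records[i].self_salience for i in members])
    cross = np.stack([records[i].cross_mean for i in members])

    n_obs = obs.sum(axis=0)
    denom = np.where(n_obs == 0, 1, n_obs)
    mean = lambda a: np.where(n_obs > 0, (a * obs).sum(axis=0) / denom, np.nan)
    return AttentionProfile(
        group_id=group_id,
        weeks_before_reference=np.arange(w - 1, -1, -1),
        mean_hba1c=mean(vals),
        mean_self_attention=mean(self_sal),
        mean_cross_attention=mean(cross),
        n_observed=n_obs,
        n_instances=int(members.size),
    )


def profile_to_frame(profile: AttentionProfile) -> pd.DataFrame:
    """Tidy export, one row per week before the reference date."""
    return pd.DataFrame(
        {
            "week_before_ref": profile.weeks_before_reference,
            "mean_hba1c": profile.mean_hba1c,
            "mean_self_attn": profile.mean_self_attention,
            "mean_cross_attn": profile.mean_cross_attention,
            "n": profile.n_observed,
        }
    )


def plot_profiles(profiles: list[AttentionProfile], path=None):
    """Three-panel figure mirroring the group-averaged attention analysis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    panels = ("mean_hba1c", "mean_self_attention", "mean_cross_attention")
    titles = ("Average HbA1c (%)", "Average self-attention weight", "Average cross-attention weight")
    for ax, attr, title in zip(axes, panels, titles):
        for prof in profiles:
            ax.plot(prof.weeks_before_reference, getattr(prof, attr), label=prof.group_id)
        ax.set_ylabel(title)
    axes[-1].set_xlabel("Weeks before reference date")
    axes[-1].invert_xaxis()
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
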