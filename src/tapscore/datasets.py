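"""Loaders that map externally released feature/rating tables onto the
package schemas.

The study behind this package released its extracted per-video features and
clinical ratings (not the raw videos) in CSV form.  These loaders adapt such
tables to the :mod:`tapscore` schemas so they can serve as an optional
benchmark input.  Because released column headings vary, each loader takes
an explicit ``column_map`` from source column names to the target schema;
sensible defaults cover identity-named columns.

Nothing here downloads anything: callers supply a local path.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

#: target schema -> candidate source column names, tried in order
_FEATURE_KEY_CANDIDATES = {
    "participant_id": ["participant_id", "subject_id", "patient_id", "Participant", "id"],
    "video_id": ["video_id", "filename", "file", "video"],
    "hand": ["hand", "hand_category", "side"],
    "label": ["label", "severity", "rating", "ground_truth", "score"],
}

_RATING_CANDIDATES = {
    "video_id": ["video_id", "filename", "file", "video"],
    "hand": ["hand", "hand_category", "side"],
    "rater_id": ["rater_id", "rater", "annotator"],
    "role": ["role", "rater_type", "expertise"],
    "rating": ["rating", "score", "severity"],
    "difficulty_flag": ["difficulty_flag", "difficult", "difficulty", "flagged"],
}


def _resolve(df: pd.DataFrame, candidates: dict, column_map: dict | None, required: set) -> dict:
    column_map = column_map or {}
    resolved = {}
    for target, options in candidates.items():
        if target in column_map:
            src = column_map[target]
            if src not in df.columns:
                raise SchemaError(f"mapped column {src!r} (for {target!r}) not in file")
            resolved[target] = src
            continue
        for opt in options:
            if opt in df.columns:
                resolved[target] = opt
                break
    missing = required - set(resolved)
    if missing:
        raise SchemaError(
            f"could not locate columns for {sorted(missing)}; "
            f"pass column_map={{target: source_column}}"
        )
    return resolved


def load_feature_table(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a released per-video feature table into the package schema.

    Key columns are renamed to ``participant_id, video_id, hand, label``;
    every other column is kept verbatim as a feature/metadata column.
    """
    df = pd.read_csv(path)
    resolved = _resolve(df, _FEATURE_KEY_CANDIDATES, column_map,
                        required={"video_id", "label"})
    out = df.rename(columns={v: k for k, v in resolved.items()})
    if "participant_id" not in out.columns:
        out["participant_id"] = out["video_id"].astype(str).str.replace(
            r"_(left|right).*$", "", regex=True
        )
    if "hand" not in out.columns:
        out["hand"] = out["video_id"].astype(str).str.extract(r"(left|right)", expand=False)
    return out


def load_ratings_table(path: str | Path, column_map: dict | None = None,
                       expert_raters: list[str] | None = None) -> pd.DataFrame:
    """Load a released ratings table into the long ratings schema.

    Accepts either an already-long table (one row per rating) or a wide one
    (one column per rater, named in ``expert_raters``/others), which is
    melted.  Raters listed in ``expert_raters`` get role ``expert``; all
    others ``nonexpert``.
    """
    df = pd.read_csv(path)
    try:
        resolved = _resolve(df, _RATING_CANDIDATES, column_map,
                            required={"video_id", "rater_id", "rating"})
        out = df.rename(columns={v: k for k, v in resolved.items()})
    except SchemaError:
        # wide layout: melt rater columns
        key = _resolve(df, {"video_id": _RATING_CANDIDATES["video_id"]}, column_map,
                       required={"video_id"})
        vid = key["video_id"]
        rater_cols = [c for c in df.columns if c != vid]
        if not rater_cols:
            raise
        out = df.melt(id_vars=vid, value_vars=rater_cols,
                      var_name="rater_id", value_name="rating")
        out = out.rename(columns={vid: "video_id"})
    if "role" not in out.columns:
        experts = set(expert_raters or [])
        out["role"] = out["rater_id"].map(lambda r: "expert" if r in experts else "nonexpert")
    if "hand" not in out.columns:
        out["hand"] = out["video_id"].astype(str).str.extract(r"(left|right)", expand=False)
    if "difficulty_flag" not in out.columns:
        out["difficulty_flag"] = False
    out["difficulty_flag"] = out["difficulty_flag"].fillna(False).astype(bool)
    return out.dropna(subset=["rating"]).reset_index(drop=True)
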