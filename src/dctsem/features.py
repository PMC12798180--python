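"""The 65 Binder semantic dimensions and named sub-domains.

The Binder feature set assigns every word a rating (roughly 0-6) on 65
experience-based dimensions spanning sensory, motor, spatial, temporal,
causal, social, cognitive, emotional and attentional components of meaning.
These names index every semantic-profile matrix in the package.
"""

from __future__ import annotations

BINDER_FEATURES: tuple[str, ...] = (
    "Vision", "Bright", "Dark", "Color", "Pattern", "Large", "Small",
    "Motion", "Biomotion", "Fast", "Slow", "Shape", "Complexity", "Face",
    "Body", "Touch", "Temperature", "Texture", "Weight", "Pain",
    "Audition", "Loud", "Low", "High", "Sound", "Music", "Speech",
    "Taste", "Smell", "Head", "UpperLimb", "LowerLimb", "Practice",
    "Landmark", "Path", "Scene", "Near", "Toward", "Away", "Number",
    "Time", "Duration", "Long", "Short", "Caused", "Consequential",
    "Social", "Human", "Communication", "Self", "Cognition", "Benefit",
    "Harm", "Pleasant", "Unpleasant", "Happy", "Sad", "Angry",
    "Disgusted", "Fearful", "Surprised", "Drive", "Needs", "Attention",
    "Arousal",
)

N_FEATURES = len(BINDER_FEATURES)
assert N_FEATURES == 65

# Emotion-domain features that are mutually correlated across words: a word
# high on one negative-emotion dimension tends to be high on the others and
# low on the positive ones.  This multicollinearity is what the tree-ensemble
# / regularized models downstream have to tolerate.
NEGATIVE_EMOTION: tuple[str, ...] = (
    "Pain", "Unpleasant", "Sad", "Angry", "Disgusted", "Fearful", "Harm",
)
POSITIVE_EMOTION: tuple[str, ...] = ("Pleasant", "Happy", "Benefit")
EMOTION_BLOCK: tuple[str, ...] = NEGATIVE_EMOTION + POSITIVE_EMOTION

# Default planted group-effect template for synthetic cohorts: the depression
# group leans proximal on negative-emotion features and distal on
# positive-emotion features.  Weights are log-odds per SD of the feature.
DEFAULT_PLANTED_POSITIVE: tuple[str, ...] = (
    "Sad", "Fearful", "Unpleasant", "Pain", "Disgusted", "Harm",
)
DEFAULT_PLANTED_NEGATIVE: tuple[str, ...] = (
    "Happy", "Pleasant", "Benefit", "Drive",
)

FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(BINDER_FEATURES)}
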