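"""Closed vocabularies for the field-trial record schema.

Destructive-sampling records describe one weevil each: which treatment arm
its stump received, its developmental stage, and the infection outcome
scored in situ and after two weeks of laboratory monitoring.
"""

# Treatment arms of the randomised-block trial; control is always first and
# is the reference level of every model.
TREATMENTS = ("control", "fungi", "halfmix", "nematodes")

# Infection outcome of one destructively sampled weevil.
OUTCOMES = ("alive", "nematode_killed", "fungus_killed", "indeterminate")

# Developmental stage at sampling time.
STAGES = ("larva", "pupa", "adult")

# Categorical fields of a weevil record, with their declared level order.
FIELD_LEVELS = {
    "treatment": TREATMENTS,
    "outcome": OUTCOMES,
    "stage": STAGES,
}

# Which kill outcome each treatment's agent produces (for agent-specific
# mortality definitions).  The combined arm counts either agent's kill.
AGENT_KILLS = {
    "fungi": ("fungus_killed",),
    "nematodes": ("nematode_killed",),
    "halfmix": ("nematode_killed", "fungus_killed"),
}
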