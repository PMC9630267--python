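# Clinical-synopsis phrase lists used for phenotype flagging.
#
# Matching is case-insensitive substring search without negation handling
# (documented limitation: "no seizures" still matches "seizures").
# Edit freely; each flag needs a non-empty list.
intellectual_disability:
  - intellectual disability
  - mental retardation
  - intellectual deficiency
  - cognitive impairment
  - global developmental delay
seizures:
  - seizure
  - epilepsy
  - epileptic
  - infantile spasms
language:
  - impaired language development
  - speech delay
  - language delay
  - absent speech
  - delayed speech
motor:
  - impaired motor development
  - motor delay
  - delayed walking
  - delayed motor milestones
spasticity:
  - spasticity
  - spastic paraplegia
  - spastic tetraplegia
ataxia:
  - ataxia
  - ataxic gait
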