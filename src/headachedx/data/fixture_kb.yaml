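# Bundled migbase-style knowledge base (synthetic fixture).
#
# Vocabulary: the discrete attribute schema of the public migbase headache
# questionnaire dataset (duration buckets A-J by attack length in seconds,
# location, severity, characterisation, previous-attack buckets, and the
# binary symptom battery folded into one set-valued attribute).
#
# Concepts: simplified ICHD-3 diagnostic criteria for the three primary
# headache disorders, written by the package authors as a test/demo fixture.
# They are deliberately mutually exclusive (location alone separates the
# classes) so that constraint-consistent samples are perfectly separable.
attributes:
  - name: duration
    kind: ordinal-categorical
    domain: [A, B, C, D, E, F, G, H, I, J]
  - name: location
    kind: nominal-categorical
    domain: [unilateral, bilateral, orbital]
  - name: headache_days
    kind: ordinal-categorical
    domain: [none, lt1, d1_14, d7_365, gt14, gt365]
  - name: severity
    kind: ordinal-categorical
    domain: [mild, moderate, severe]
  - name: characterisation
    kind: nominal-categorical
    domain: [pressing, pulsating, stabbing]
  - name: previous_attacks
    kind: ordinal-categorical
    domain: [a2_4, a5_9, a10_19, a20plus]
  - name: aura_duration
    kind: ordinal-categorical
    domain: [none, hour, day]
  - name: symptoms
    kind: set-valued
    domain:
      - nausea
      - vomiting
      - photophobia
      - phonophobia
      - aggravation
      - conjunctival_injection
      - lacrimation
      - pericranial
      - nasal_congestion
      - rhinorrhoea
      - eyelid_oedema
      - forehead_facial_sweating
      - miosis
      - ptosis
      - speech_disturbance
      - dysarthria
      - hemiplegic
      - visual_symptoms
      - sensory_symptoms
      - homonymous_symptoms
      - agitation
      - motor_weakness
      - vertigo
      - tinnitus
      - hypacusia
      - diplopia
      - ataxia
      - decreased_consciousness
      - nasal_symptoms
      - paraesthesias
      - aura_development
      - headache_with_aura
concepts:
  - label: migraine
    restrictions:
      # attacks lasting 4-72 h (bucket H)
      - {attribute: duration, kind: fixed, values: [H]}
      - {attribute: location, kind: fixed, values: [unilateral]}
      - {attribute: characterisation, kind: fixed, values: [pulsating]}
      - {attribute: severity, kind: one-of, values: [moderate, severe]}
      - {attribute: previous_attacks, kind: one-of, values: [a5_9, a10_19, a20plus]}
      # ICHD demands nausea and/or vomiting, or photophobia plus phonophobia;
      # approximated conjunctively as "at least two of the four".
      - attribute: symptoms
        kind: at-least-m-of
        values: [nausea, vomiting, photophobia, phonophobia]
        m: 2
  - label: tension
    restrictions:
      # attacks lasting 30 min to 7 days (buckets F-I)
      - {attribute: duration, kind: one-of, values: [F, G, H, I]}
      - {attribute: location, kind: fixed, values: [bilateral]}
      - {attribute: characterisation, kind: fixed, values: [pressing]}
      - {attribute: severity, kind: one-of, values: [mild, moderate]}
      # no nausea or vomiting; at most mild photophobia / pericranial tenderness
      - {attribute: symptoms, kind: subset-of, values: [photophobia, pericranial]}
  - label: cluster
    restrictions:
      # attacks lasting 15-180 min (buckets E-F)
      - {attribute: duration, kind: one-of, values: [E, F]}
      - {attribute: location, kind: fixed, values: [orbital]}
      - {attribute: severity, kind: fixed, values: [severe]}
      - {attribute: previous_attacks, kind: one-of, values: [a5_9, a10_19, a20plus]}
      # at least one ipsilateral autonomic symptom
      - attribute: symptoms
        kind: at-least-m-of
        values:
          - conjunctival_injection
          - lacrimation
          - nasal_congestion
          - rhinorrhoea
          - eyelid_oedema
          - forehead_facial_sweating
          - miosis
          - ptosis
        m: 1
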