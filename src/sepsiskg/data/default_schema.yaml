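# Default sepsis knowledge-graph ontology.
#
# Nine entity concepts and eight core semantic relations, as used for the
# multicenter sepsis knowledge graph, plus one extension relation
# ("subtype of") so that every label the extraction prompt may return has a
# canonical target. Attribute lists and meanings are reproduced verbatim from
# the source concept tables.
version: "1.0"

entity_types:
  - name: Diseases
    attributes: [canonical name, concept ID, TUIs, definition, reference, synonyms]
    description: >-
      Disease is an atypical life process that occurs due to disrupted
      self-regulation in the body under specific conditions after exposure to
      pathogenic damage.
  - name: Symptoms
    attributes: [canonical name, concept ID, TUIs, duration, severity, frequency, temporal pattern]
    description: >-
      Subjective atypical sensations or objective pathological changes in a
      patient resulting from a series of physiological, metabolic, and
      morphological abnormalities during the disease process.
  - name: Imaging examination
    attributes: [canonical name, concept ID, TUIs, type, body region, imaging findings]
    description: >-
      Imaging examination is a technique used to visualize the interior of a
      body for clinical analysis and medical intervention.
  - name: Biomarkers
    attributes: [canonical name, concept ID, TUIs, biomarker type, reference, synonyms, cut-off value, sensitivity, specificity]
    description: >-
      Measurable substances in the body used to indicate physiological status,
      the presence of disease, or disease progression.
  - name: Laboratory test
    attributes: [canonical name, concept ID, TUIs, normal range, unit, measured value]
    description: >-
      Physical or chemical examinations conducted in a laboratory to determine
      the content, nature, concentration, quantity, and other characteristics
      of submitted substances.
  - name: Subtypes
    attributes: [canonical name, concept ID, TUIs, definition, reference, synonyms]
    description: >-
      Subdivisions within a category or group based on specific features or
      characteristics. For example, disease subtypes may indicate different
      pathological features or symptom presentations.
  - name: Pathogenic mechanism
    # "UIs" (not "TUIs") is carried over as printed in the source table.
    attributes: [canonical name, concept ID, UIs, type, infection source, reference, biomarkers, guidelines]
    description: >-
      Biological or biochemical processes leading to the occurrence of disease,
      including factors such as pathogen infection and genetic mutations.
  - name: Pharmacotherapy
    attributes: [canonical name, concept ID, TUIs, medication name, drug class, dosage, duration of treatment, adverse effects, drug interactions, formulations]
    description: >-
      Substances used for preventing, treating, and diagnosing diseases. In
      theory, drugs encompass chemical substances that can influence the
      physiological functions and cellular metabolic activities of the body's
      organs.
  - name: Surgery
    attributes: [canonical name, concept ID, TUIs, anesthesia type, guidelines, complications, recovery time, level]
    description: >-
      A procedure involving the use of instruments, performed by a surgeon or
      other specialized personnel, to enter the human body or other biological
      tissues.

relation_types:
  - canonical_name: complications
    prompt_labels: [Complications, has complication]
    default_subject_type: Diseases
    default_object_type: Diseases
    meaning: >-
      Disease development may give rise to another disease or the occurrence
      of additional symptoms.
  - canonical_name: has symptom
    prompt_labels: [Clinical Presentation]
    default_subject_type: Diseases
    default_object_type: Symptoms
    meaning: Describing the correlation between diseases and symptoms.
  - canonical_name: recommended imaging examination
    prompt_labels: [Imaging examination]
    default_subject_type: Diseases
    default_object_type: Imaging examination
    meaning: Recommended imaging examination for patients with sepsis.
  - canonical_name: the related biomarkers
    prompt_labels: [biomarker]
    default_subject_type: Diseases
    default_object_type: Biomarkers
    meaning: Biomarkers associated with sepsis.
  - canonical_name: treat
    prompt_labels: [Surgical treatment]
    default_subject_type: Diseases
    default_object_type: Surgery
    meaning: Surgical treatment modalities associated with sepsis.
  - canonical_name: recommended laboratory tests
    prompt_labels: [laboratory testing]
    default_subject_type: Diseases
    default_object_type: Laboratory test
    meaning: Routine laboratory tests associated with sepsis.
  - canonical_name: caused by
    prompt_labels: [pathogenesis]
    default_subject_type: Diseases
    default_object_type: Pathogenic mechanism
    meaning: The underlying factors contributing to the onset of sepsis.
  - canonical_name: recommended medication
    prompt_labels: [Medication]
    default_subject_type: Diseases
    default_object_type: Pharmacotherapy
    meaning: Pharmacological interventions in the treatment process of sepsis.
  # Extension: the extraction prompt can return "subclass", which has no core
  # relation; it is mapped to a disease-to-subtype relation so the information
  # is preserved rather than dropped. Remove this block to disable.
  - canonical_name: subtype of
    prompt_labels: [subclass]
    default_subject_type: Diseases
    default_object_type: Subtypes
    extension: true
    meaning: Links a disease to one of its defined subtypes.
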