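# pathcdm bundled concept dictionary, version 1.
#
# Maps canonical biomarker/test names, normalized result categories,
# (diagnosis, site) pairs and report sections to OMOP-standard concept
# identifiers (LOINC for measurements, SNOMED CT for values and
# relationships, ICD-O-3 for oncology diagnoses).  Identifiers that are not
# part of the standard vocabularies are locally minted in the 2000000xxx
# range (or reuse the SNOMED source code) and carry `custom: true`.
# Rows with an empty `code` are mapped concepts whose LOINC code is not
# recorded here yet (documented TODO rows).
version: 1

aliases:
  # Qualifier stripping already turns "EGFR (GI)" into "EGFR"; aliases catch
  # spelling variants that survive cleaning.
  "MLH1": "hMLH1"
  "MSH2": "hMSH2"
  "MSH6": "hMSH6"
  "Microsatellite instability": "MSI"
  "KI-67": "Ki-67"
  "P53": "p53"

measurements:
  # Immunohistochemistry biomarkers (LOINC / local measurement concepts).
  - {name: "EGFR", concept_id: 3016231, code: "32581-1", concept_name: "Epidermal growth factor receptor Ag [Presence] in Tissue by Immune stain"}
  - {name: "hMLH1", concept_id: 21493968, code: "", concept_name: "MLH1 protein expression in Tissue by Immune stain"}
  - {name: "Ki-67", concept_id: 3046605, code: "", concept_name: "Ki-67 nuclear Ag [Presence] in Tissue by Immune stain"}
  - {name: "PTEN", concept_id: 21493983, code: "", concept_name: "PTEN protein expression in Tissue by Immune stain"}
  - {name: "p53", concept_id: 3017031, code: "", concept_name: "p53 Ag [Presence] in Tissue by Immune stain"}
  - {name: "BRAF", concept_id: 21493982, code: "", concept_name: "BRAF protein expression in Tissue by Immune stain"}
  - {name: "CD3", concept_id: 3027870, code: "", concept_name: "CD3 Ag [Presence] in Tissue by Immune stain"}
  - {name: "C-erbB2", concept_id: 3019066, code: "", concept_name: "Her2 [Presence] in Tissue by Immune stain"}
  - {name: "CD20", concept_id: 3026213, code: "", concept_name: "CD20 Ag [Presence] in Tissue by Immune stain"}
  - {name: "hMSH2", concept_id: 21493969, code: "", concept_name: "MSH2 protein expression in Tissue by Immune stain"}
  - {name: "bcl-6", concept_id: 3051327, code: "", concept_name: "Bcl-6 [Presence] in Tissue by Immune stain"}
  - {name: "hMSH6", concept_id: 21493970, code: "", concept_name: "MSH6 protein expression in Tissue by Immune stain"}
  - {name: "PMS2", concept_id: 21493971, code: "", concept_name: "PMS2 protein expression in Tissue by Immune stain"}
  - {name: "Cyclin D1", concept_id: 21492142, code: "", concept_name: "Cyclin D1 [Presence] in Tissue by Immune stain"}
  - {name: "Desmin", concept_id: 3002495, code: "", concept_name: "Desmin Ag [Presence] in Tissue by Immune stain"}
  - {name: "CD8", concept_id: 3052827, code: "", concept_name: "CD8 Ag [Presence] in Tissue by Immune stain"}
  - {name: "CD10", concept_id: 3041284, code: "", concept_name: "CD10 Ag [Presence] in Tissue by Immune stain"}
  - {name: "Cytokeratin", concept_id: 3040360, code: "", concept_name: "Cytokeratin [Presence] in Tissue by Immune stain"}
  - {name: "Synaptophysin", concept_id: 3006921, code: "", concept_name: "Synaptophysin Ag [Presence] in Tissue by Immune stain"}
  - {name: "MUM-1", concept_id: 3032734, code: "", concept_name: "MUM1 protein [Presence] in Tissue by Immune stain"}
  # Molecular study tests (test-level LOINC concepts).
  - {name: "NRAS mutation", concept_id: 3001274, code: "21719-0", concept_name: "NRAS gene mutations found [Identifier] in Blood or Tissue by Molecular genetics method Nominal"}
  - {name: "KRAS mutation", concept_id: 36203353, code: "85509-8", concept_name: "KRAS gene mutations found [Identifier] in Blood or Tissue by Molecular genetics method Nominal"}
  - {name: "MSI", concept_id: 3047348, code: "43368-0", concept_name: "Microsatellite instability [Presence] in Tissue by Immune stain"}
  - {name: "BRAF mutation", concept_id: 40761583, code: "58483-9", concept_name: "BRAF gene mutations found [Identifier] in Blood or Tissue by Molecular genetics method Nominal"}

values:
  # SNOMED CT qualifier values; "Positive" is OMOP concept 9191 (SNOMED
  # source code 10828004), "Negative" is 9189.  MSI classes are locally
  # minted pending standard answer-list concepts.
  - {category: "positive", concept_id: 9191}
  - {category: "negative", concept_id: 9189}
  - {category: "msi_high", concept_id: 2000000101}
  - {category: "msi_low", concept_id: 2000000102}
  - {category: "mss", concept_id: 2000000103}
  - {category: "unknown", concept_id: 0}

conditions:
  # ICD-O-3 keyed oncology diagnoses; keys are matched lowercased with
  # collapsed whitespace.  `site: ""` is the site-agnostic fallback.
  - {diagnosis: "tubular adenoma, nos", site: "", source_concept_id: 44498791, standard_concept_id: 2000000211, icdo3: "8211/0", custom: true}
  - {diagnosis: "adenocarcinoma, nos", site: "sigmoid colon", source_concept_id: 2000000201, standard_concept_id: 2000000202, icdo3: "8140/3-C18.7", custom: true}
  - {diagnosis: "adenocarcinoma, nos", site: "", source_concept_id: 2000000203, standard_concept_id: 2000000204, icdo3: "8140/3", custom: true}
  - {diagnosis: "tubulovillous adenoma, nos", site: "", source_concept_id: 2000000205, standard_concept_id: 2000000206, icdo3: "8263/0", custom: true}
  - {diagnosis: "mucinous adenocarcinoma", site: "", source_concept_id: 2000000207, standard_concept_id: 2000000208, icdo3: "8480/3", custom: true}
  - {diagnosis: "neuroendocrine tumor, nos", site: "", source_concept_id: 2000000209, standard_concept_id: 2000000210, icdo3: "8240/3", custom: true}

sections:
  # NOTE_NLP section concepts: one per report type, and one per molecular
  # test (molecular sections are keyed by test name).
  - {key: "surgical", concept_id: 3025891, source_value: "Pathology reports of surgical specimen"}
  - {key: "ihc", concept_id: 40758358, source_value: "Immunochemistry test report"}
  - {key: "NRAS mutation", concept_id: 3001274, source_value: "N-ras Gene sequencing test"}
  - {key: "KRAS mutation", concept_id: 36203353, source_value: "K-ras Gene sequencing test"}
  - {key: "MSI", concept_id: 3047348, source_value: "Microsatellite instability test"}
  - {key: "BRAF mutation", concept_id: 40761583, source_value: "B-raf Gene sequencing test"}

relationships:
  # SNOMED relationship pair linking a specimen to the facts derived from
  # it; local ids reuse the SNOMED source codes (no standard concept id is
  # recorded here), hence custom.
  specimen_source_identity: {concept_id: 118169006, inverse_concept_id: 116686009, custom: true}
  has_specimen: {concept_id: 116686009, inverse_concept_id: 118169006, custom: true}

domains:
  # OMOP Domain concepts used in FACT_RELATIONSHIP domain_concept_id fields.
  Condition: 19
  Measurement: 21
  Specimen: 36

lexicons:
  molecular_negative: ["negative", "not detected", "none identified"]
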