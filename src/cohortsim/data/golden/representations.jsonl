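{"document_id": "doc000", "patient_id": "pat000", "total_terms": 8, "per_label": {"immune": [["commun_immune_t1", 1]], "musculoskeletal": [["osteoporosis_musculoskeletal_t2", 1], ["osteoporosis_musculoskeletal_t1", 1]], "nutritional": [["osteoporosis_nutritional_t1", 1], ["osteoporosis_nutritional_t3", 2]], "urogenital": [["commun_urogenital_t2", 1], ["commun_urogenital_t1", 1]]}}
{"document_id": "doc001", "patient_id": "pat001", "total_terms": 8, "per_label": {"immune": [["nephritis_sle_immune_t1", 1], ["nephritis_sle_immune_t2", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 2], ["commun_musculoskeletal_t1", 1]], "nutritional": [["commun_nutritional_t2", 1]], "urogenital": [["nephritis_sle_urogenital_t3", 1], ["nephritis_sle_urogenital_t1", 1]]}}
{"document_id": "doc002", "patient_id": "pat002", "total_terms": 8, "per_label": {"immune": [["commun_immune_t1", 2], ["commun_immune_t2", 1]], "musculoskeletal": [["osteoporosis_musculoskeletal_t1", 1]], "nutritional": [["osteoporosis_nutritional_t3", 2], ["osteoporosis_nutritional_t1", 1]], "urogenital": [["commun_urogenital_t1", 1]]}}
{"document_id": "doc003", "patient_id": "pat003", "total_terms": 10, "per_label": {"immune": [["nephritis_sle_immune_t2", 2], ["nephritis_sle_immune_t3", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 2]], "nutritional": [["commun_nutritional_t0", 1], ["commun_nutritional_t1", 1]], "urogenital": [["nephritis_sle_urogenital_t0", 2], ["nephritis_sle_urogenital_t2", 1]]}}
{"document_id": "doc004", "patient_id": "pat004", "total_terms": 8, "per_label": {"immune": [["nephritis_sle_immune_t2", 1], ["nephritis_sle_immune_t1", 1], ["nephritis_sle_immune_t3", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 2]], "nutritional": [["commun_nutritional_t0", 1]], "urogenital": [["nephritis_sle_urogenital_t0", 1], ["nephritis_sle_urogenital_t2", 1]]}}
{"document_id": "doc005", "patient_id": "pat005", "total_terms": 7, "per_label": {"immune": [["commun_immune_t1", 1], ["commun_immune_t0", 1]], "musculoskeletal": [["osteoporosis_musculoskeletal_t2", 2]], "nutritional": [["osteoporosis_nutritional_t2", 1], ["osteoporosis_nutritional_t3", 1]], "urogenital": [["commun_urogenital_t2", 1]]}}
{"document_id": "doc006", "patient_id": "pat006", "total_terms": 6, "per_label": {"immune": [["nephritis_sle_immune_t3", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 1]], "nutritional": [["commun_nutritional_t1", 1], ["commun_nutritional_t0", 2]], "urogenital": [["nephritis_sle_urogenital_t0", 1]]}}
{"document_id": "doc007", "patient_id": "pat007", "total_terms": 5, "per_label": {"immune": [["nephritis_sle_immune_t3", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 1]], "nutritional": [["commun_nutritional_t0", 2]], "urogenital": [["nephritis_sle_urogenital_t3", 1]]}}
{"document_id": "doc008", "patient_id": "pat008", "total_terms": 6, "per_label": {"immune": [["commun_immune_t2", 1]], "musculoskeletal": [["osteoporosis_musculoskeletal_t1", 1], ["osteoporosis_musculoskeletal_t0", 2]], "nutritional": [["osteoporosis_nutritional_t3", 1]], "urogenital": [["commun_urogenital_t2", 1]]}}
{"document_id": "doc009", "patient_id": "pat009", "total_terms": 6, "per_label": {"immune": [["commun_immune_t1", 1]], "musculoskeletal": [["osteoporosis_musculoskeletal_t1", 1], ["osteoporosis_musculoskeletal_t0", 2]], "nutritional": [["osteoporosis_nutritional_t3", 1]], "urogenital": [["commun_urogenital_t2", 1]]}}
{"document_id": "doc010", "patient_id": "pat010", "total_terms": 7, "per_label": {"immune": [["nephritis_sle_immune_t2", 1]], "musculoskeletal": [["commun_musculoskeletal_t0", 1]], "nutritional": [["commun_nutritional_t0", 2], ["commun_nutritional_t2", 1]], "urogenital": [["nephritis_sle_urogenital_t1", 1], ["nephritis_sle_urogenital_t0", 1]]}}
{"document_id": "doc011", "patient_id": "pat011", "total_terms": 9, "per_label": {"immune": [["commun_immune_t1", 2]], "musculoskeletal": [["osteoporosis_musculoskeletal_t1", 1]], "nutritional": [["osteoporosis_nutritional_t3", 2], ["osteoporosis_nutritional_t1", 1]], "urogenital": [["commun_urogenital_t1", 1], ["commun_urogenital_t2", 1], ["commun_urogenital_t0", 1]]}}
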