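"""Export a classified patient as RDF triples (Turtle).

The export uses the copd: vocabulary (copd:isInHealthCondition,
copd:hasRecommendation, copd:FEV1, copd:nutritionalRiskIndex,
copd:proteinsGrams, copd:regularRecommendedCaloricIntake, ...) so the
output can sit next to an OWL ontology of the same domain.
"""

import nutricopd as nc

patient = nc.make_archetype(
    nc.Phenotype.underweight, nc.CopdStage.I, nc.NriClass.severe,
    nc.SarcopeniaLevel.severe, cachectic=True, gender=nc.Gender.female,
    patient_id="001")
cls, rec, _ = nc.recommend(patient)
print(nc.export_triples(patient, cls, rec))
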