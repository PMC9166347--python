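# Vocabulary subset used by diaet knowledge bases.
# A clinical trial has arms; each arm names its drug and carries endpoint
# results and adverse-event counts; the trial carries filterable metadata.
@prefix ctro: <https://w3id.org/diaet/ctro#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .

ctro:ClinicalTrial a rdfs:Class ;
    rdfs:comment "A randomized controlled trial comparing drug treatments." .

ctro:hasArm a rdf:Property ;
    rdfs:comment "Links a trial to one of its interventional arms (a named IRI)." .

ctro:hasDrugName a rdf:Property ;
    rdfs:comment "Drug name of an arm, as a string literal; matched case-insensitively after whitespace normalization." .

ctro:hasEndpointResult a rdf:Property ;
    rdfs:comment "Links an arm to one endpoint-result node (a named IRI)." .

ctro:hasEndpointId a rdf:Property ;
    rdfs:comment "Identifier of the clinical endpoint measured, e.g. diurnal_IOP or HbA1c." .

ctro:hasBaselineValue a rdf:Property ;
    rdfs:comment "Endpoint value at baseline (numeric literal, endpoint units)." .

ctro:hasChangeValue a rdf:Property ;
    rdfs:comment "Signed change from baseline; negative means reduction. When absent, derived as hasFinalValue - hasBaselineValue." .

ctro:hasFinalValue a rdf:Property ;
    rdfs:comment "Endpoint value at end of follow-up (numeric literal)." .

ctro:hasUnit a rdf:Property ;
    rdfs:comment "Measurement unit of the endpoint values, identical across the arms of one trial." .

ctro:isSignificant a rdf:Property ;
    rdfs:comment "Whether the trial reported the between-arm difference as statistically significant (boolean; carried, not used by the superiority criteria)." .

ctro:hasAdverseEvent a rdf:Property ;
    rdfs:comment "Links an arm to one adverse-event count node (a named IRI)." .

ctro:hasEventId a rdf:Property ;
    rdfs:comment "Identifier of the adverse event, e.g. conjunctival_hyperemia." .

ctro:hasNumberAffected a rdf:Property ;
    rdfs:comment "Number of participants in the arm affected by the event (non-negative integer)." .

ctro:hasArmSize a rdf:Property ;
    rdfs:comment "Number of participants in the arm; enables incidence-proportion comparison." .

ctro:hasPublicationYear a rdf:Property ;
    rdfs:comment "Publication year of the trial report (integer)." .

ctro:hasDurationWeeks a rdf:Property ;
    rdfs:comment "Follow-up duration in weeks (non-negative number)." .

ctro:hasNumberOfParticipants a rdf:Property ;
    rdfs:comment "Total number of randomized participants (non-negative integer)." .

ctro:hasMeanAge a rdf:Property ;
    rdfs:comment "Mean participant age in years (non-negative number, optional)." .
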