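@prefix drugs: <urn:ontorx:drugs:> .
@prefix dss:   <urn:ontorx:dss:> .
@prefix local: <urn:ontorx:local:> .
@prefix owl:   <http://www.w3.org/2002/07/owl#> .
@prefix rdfs:  <http://www.w3.org/2000/01/rdf-schema#> .

# ---------------------------------------------------------------------------
# Terminological schema (T-Box).  Authored once and shipped with the
# package; only the assertional half (A-Box) is compiled from data.
# ---------------------------------------------------------------------------

# --- drugs ontology: identification & technical data of medicinal products

drugs:MedicinalProduct a owl:Class ; rdfs:label "Medicinal product" .
drugs:VTM a owl:Class ; rdfs:subClassOf drugs:MedicinalProduct ;
    rdfs:label "Virtual therapeutic moiety" .
drugs:VMP a owl:Class ; rdfs:subClassOf drugs:MedicinalProduct ;
    rdfs:label "Virtual medicinal product" .
drugs:AMP a owl:Class ; rdfs:subClassOf drugs:MedicinalProduct ;
    rdfs:label "Actual medicinal product" .

drugs:PackagedMedicinalProduct a owl:Class ; rdfs:label "Packaged medicinal product" .
drugs:VMPP a owl:Class ; rdfs:subClassOf drugs:PackagedMedicinalProduct ;
    rdfs:label "Virtual medicinal product pack" .
drugs:AMPP a owl:Class ; rdfs:subClassOf drugs:PackagedMedicinalProduct ;
    rdfs:label "Actual medicinal product pack" .

drugs:Matter a owl:Class ; rdfs:label "Matter" .
drugs:Ingredient a owl:Class ; rdfs:subClassOf drugs:Matter ;
    rdfs:label "Product ingredient" .
drugs:ChemicalGroup a owl:Class ; rdfs:subClassOf drugs:Matter ;
    rdfs:label "Chemical group" .

drugs:Route a owl:Class ; rdfs:label "Drug route" .
drugs:DoseForm a owl:Class ; rdfs:label "Drug dose form" .
drugs:Unit a owl:Class ; rdfs:label "Unit" .
drugs:Frequency a owl:Class ; rdfs:label "Frequency" .

drugs:hasIngredient a owl:ObjectProperty ;
    rdfs:domain drugs:MedicinalProduct ; rdfs:range drugs:Ingredient .
drugs:hasVTM a owl:ObjectProperty ;
    rdfs:domain drugs:VMP ; rdfs:range drugs:VTM .
drugs:hasVMP a owl:ObjectProperty ;
    rdfs:domain drugs:AMP ; rdfs:range drugs:VMP .
drugs:hasRoute a owl:ObjectProperty ;
    rdfs:domain drugs:MedicinalProduct ; rdfs:range drugs:Route .
drugs:hasDoseForm a owl:ObjectProperty ;
    rdfs:domain drugs:MedicinalProduct ; rdfs:range drugs:DoseForm .
drugs:hasMember a owl:ObjectProperty ;
    rdfs:domain drugs:ChemicalGroup ; rdfs:range drugs:Ingredient .
drugs:memberOf a owl:ObjectProperty ; owl:inverseOf drugs:hasMember .
drugs:packOf a owl:ObjectProperty ;
    rdfs:domain drugs:PackagedMedicinalProduct ; rdfs:range drugs:MedicinalProduct .

drugs:hasATC a owl:DatatypeProperty .
drugs:strengthValue a owl:DatatypeProperty .
drugs:strengthUnit a owl:DatatypeProperty .
drugs:state a owl:DatatypeProperty .
drugs:packSize a owl:DatatypeProperty .
drugs:price a owl:DatatypeProperty .
drugs:unitDimension a owl:DatatypeProperty .
drugs:factorToBase a owl:DatatypeProperty .
drugs:administrationsPer24h a owl:DatatypeProperty .

# --- dss ontology: appropriateness drug data

dss:AppropriatenessCriterion a owl:Class ; rdfs:label "Appropriateness criteria" .
dss:DrugInteraction a owl:Class ; rdfs:subClassOf dss:AppropriatenessCriterion ;
    rdfs:label "Drug interaction" .
dss:DrugAppropriateness a owl:Class ; rdfs:subClassOf dss:AppropriatenessCriterion ;
    rdfs:label "Drug appropriateness" .
dss:DoseAppropriateness a owl:Class ; rdfs:subClassOf dss:DrugAppropriateness ;
    rdfs:label "Dose appropriateness" .
dss:MaximumDoseAdult a owl:Class ; rdfs:subClassOf dss:DoseAppropriateness ;
    rdfs:label "Maximum dose adult" .
dss:AppropriatenessLabTest a owl:Class ; rdfs:subClassOf dss:DrugAppropriateness ;
    rdfs:label "Appropriateness lab test" .
dss:RenalAdjustment a owl:Class ; rdfs:subClassOf dss:AppropriatenessLabTest ;
    rdfs:label "Renal adjustment" .
dss:Alert a owl:Class ; rdfs:label "Alert" .
dss:LabTest a owl:Class ; rdfs:label "Laboratory test" .

dss:ingredient a owl:ObjectProperty ;
    rdfs:domain dss:DrugAppropriateness ; rdfs:range drugs:Ingredient .
dss:route a owl:ObjectProperty ; rdfs:range drugs:Route .
dss:alert a owl:ObjectProperty ;
    rdfs:domain dss:AppropriatenessCriterion ; rdfs:range dss:Alert .
dss:labTest a owl:ObjectProperty ;
    rdfs:domain dss:AppropriatenessLabTest ; rdfs:range dss:LabTest .

dss:maxDailyDose a owl:DatatypeProperty .
dss:doseUnit a owl:DatatypeProperty .
dss:ageMin a owl:DatatypeProperty .
dss:ageMax a owl:DatatypeProperty .
dss:atcA a owl:DatatypeProperty .
dss:atcB a owl:DatatypeProperty .
dss:labUnit a owl:DatatypeProperty .
dss:gfrLow a owl:DatatypeProperty .
dss:gfrHigh a owl:DatatypeProperty .
dss:loadingDose a owl:DatatypeProperty .
dss:loadingUnit a owl:DatatypeProperty .
dss:adjustedMinDaily a owl:DatatypeProperty .
dss:adjustedMaxDaily a owl:DatatypeProperty .
dss:alertDescription a owl:DatatypeProperty .
dss:alertRecommendation a owl:DatatypeProperty .
dss:alertSource a owl:DatatypeProperty .
dss:alertLastUpdated a owl:DatatypeProperty .
dss:alertLevel a owl:DatatypeProperty .

# --- local pharmacy ontology: EHR/CPOE concepts mapped onto canonical ones

local:LocalConcept a owl:Class ; rdfs:label "Local concept" .
local:LocalDrug a owl:Class ; rdfs:subClassOf local:LocalConcept .
local:LocalRoute a owl:Class ; rdfs:subClassOf local:LocalConcept .
local:LocalUnit a owl:Class ; rdfs:subClassOf local:LocalConcept .
local:LocalFrequency a owl:Class ; rdfs:subClassOf local:LocalConcept .
local:LocalLabTest a owl:Class ; rdfs:subClassOf local:LocalConcept .
local:LocalAllergen a owl:Class ; rdfs:subClassOf local:LocalConcept .

local:mapsTo a owl:ObjectProperty ; rdfs:domain local:LocalConcept .
local:localCode a owl:DatatypeProperty .
local:localLabel a owl:DatatypeProperty .
local:domain a owl:DatatypeProperty .
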