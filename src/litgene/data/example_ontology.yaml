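# Illustrative addiction mini-ontology (hand-written example for the
# documented format; not a published keyword set). Three levels:
# category -> concept -> keywords. The "GWAS" category is reserved:
# its keywords are matched against GWAS catalog trait text.
- category: addiction stage
  concepts:
    - concept: initiation
      keywords: [initiation, acquisition, "first use"]
    - concept: relapse
      keywords: [relapse, reinstatement, craving]
    - concept: withdrawal
      keywords: [withdrawal, abstinence]
- category: drugs
  concepts:
    - concept: nicotine
      keywords: [nicotine, smoking, tobacco, cigarette]
    - concept: opioids
      keywords: [opioid, morphine, heroin, fentanyl, oxycodone]
    - concept: psychostimulants
      keywords: [cocaine, amphetamine, methamphetamine]
    - concept: alcohol
      keywords: [alcohol, ethanol]
- category: brain region
  concepts:
    - concept: striatum
      keywords: [striatum, "nucleus accumbens", striatal]
    - concept: prefrontal cortex
      keywords: ["prefrontal cortex", PFC]
    - concept: amygdala
      keywords: [amygdala, amygdalar]
- category: CNS cell type
  concepts:
    - concept: neurons
      keywords: [neuron, neurons, neuronal, interneuron]
    - concept: glial cells
      keywords: [astrocytes, microglia, oligodendrocytes]
- category: stress
  concepts:
    - concept: stress
      keywords: [stress, stressor]
    - concept: HPA axis
      keywords: [corticosterone, cortisol, CRH, ACTH, "HPA axis"]
- category: psychiatric diseases
  concepts:
    - concept: depression
      keywords: [depression, depressive, anhedonia]
    - concept: anxiety
      keywords: [anxiety, anxiogenic, anxiolytic]
- category: molecular function
  concepts:
    - concept: neurotransmission
      keywords: [dopamine, serotonin, glutamate, GABA]
    - concept: signaling
      keywords: [phosphorylation, "signal transduction", kinase]
- category: GWAS
  concepts:
    - concept: smoking traits
      keywords: [smoking, tobacco, cigarettes]
    - concept: substance dependence
      keywords: [dependence, addiction, "alcohol consumption", opioid]
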