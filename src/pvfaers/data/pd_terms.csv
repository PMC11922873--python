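family,term
indication,Parkinson's disease
indication,Idiopathic Parkinson's disease
pd_event,Parkinson's disease
dementia,Dementia
psychosis,Psychotic disorder
psychosis,Hallucination
psychosis,Hallucination visual
psychosis,Delusion
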