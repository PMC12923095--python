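task,model,increase,stable,decrease,catastrophic
sentiment,GPT,6,2,19,9
sentiment,BlueBERT,0,16,20,0
sentiment,Llama,0,19,14,3
medical_abstract,GPT,13,15,5,3
medical_abstract,BlueBERT,0,28,8,0
medical_abstract,Llama,0,15,21,0
question_answer,GPT,15,1,11,0
question_answer,Llama,4,17,6,0
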