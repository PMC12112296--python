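pt,provenance
acute kidney injury,SMQ
blood creatinine increased,SMQ
glomerulonephritis,SMQ
immune-mediated nephritis,manual
nephritis allergic,SMQ
nephropathy toxic,SMQ
nephrosclerosis,SOC
nephrotic syndrome,SMQ
proteinuria,SMQ
renal impairment,SMQ
renal tubular acidosis,SOC
renal tubular atrophy,SOC
renal tubular disorder,SOC
renal tubular injury,SOC
renal tubular necrosis,SMQ
tubulointerstitial nephritis,SMQ
anuria,SMQ
oliguria,SMQ
renal failure,SMQ
chronic kidney disease,SMQ
glomerular filtration rate decreased,SMQ
blood urea increased,SMQ
nephritis,SOC
azotaemia,SMQ
haematuria,SOC
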