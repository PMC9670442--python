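code,critical_value,description
NORM,0,Normal ECG
NT_,0,Non-specific T-wave changes
SR,0,Sinus rhythm
NDT,1,Non-diagnostic T abnormalities
LAFB,1,Left anterior fascicular block
IRBBB,1,Incomplete right bundle branch block
NST_,1,Non-specific ST changes
CRBBB,1,Complete right bundle branch block
ISC_,1,Non-specific ischemic
PACE,1,Normal functioning artificial pacemaker
1AVB,1,First degree AV block
LAO/LAE,1,Left atrial overload/enlargement
ISCLA,1,Ischemic in lateral leads
ILBBB,1,Incomplete left bundle branch block
RAO/RAE,1,Right atrial overload/enlargement
LPFB,1,Left posterior fascicular block
RVH,1,Right ventricular hypertrophy
SEHYP,1,Septal hypertrophy
STACH,1,Sinus tachycardia
PAC,1,Atrial premature complex
ABQRS,1,Abnormal QRS
HVOLT,1,High QRS voltage
INVT,1,Inverted T-waves
LOWT,1,Low amplitude T-waves
LPR,1,Prolonged PR interval
LVOLT,1,Low QRS voltages in the frontal and horizontal leads
SARRH,1,Sinus arrhythmia
SBRAD,1,Sinus bradycardia
STD_,1,Non-specific ST depression
STE_,1,Non-specific ST elevation
TAB_,1,T-wave abnormality
LVH,2,Left ventricular hypertrophy
CLBBB,2,Complete left bundle branch block
ISCAL,2,Ischemic in anterolateral leads
IVCD,2,Non-specific intraventricular conduction disturbance (block)
PVC,2,Ventricular premature complex
INJAS,2,Subendocardial injury in anteroseptal leads
ISCAS,2,Ischemic in anteroseptal leads
ISCIN,2,Ischemic in inferior leads
ISCIL,2,Ischemic in inferolateral leads
AFLT,2,Atrial flutter
AF,2,Atrial fibrillation
EL,2,Electrolytic disturbance or drug (former EDIS)
PSVT,2,Paroxysmal supraventricular tachycardia
DIG,2,Digitalis-effect
ISCAN,2,Ischemic in anterior leads
2AVB,2,Second degree AV block
INJIL,2,Subendocardial injury in inferolateral leads
INJLA,2,Subendocardial injury in lateral leads
INJIN,2,Subendocardial injury in inferior leads
BIGU,2,Bigeminal pattern (unknown origin; SV or ventricular)
PRC(S),2,Premature complex(es)
QWAVE,2,Q waves present
SVARR,2,Supraventricular arrhythmia
SVTAC,2,Supraventricular tachycardia
TRIGU,2,Trigeminal pattern (unknown origin; SV or ventricular)
VCLVH,2,Voltage criteria (QRS) for left ventricular hypertrophy
IMI,3,Inferior myocardial infarction
ASMI,3,Anteroseptal myocardial infarction
ILMI,3,Inferolateral myocardial infarction
AMI,3,Anterior myocardial infarction
ALMI,3,Anterolateral myocardial infarction
LNGQT,3,Long QT-interval
WPW,3,Wolff-Parkinson-White syndrome
LMI,3,Lateral myocardial infarction
IPLMI,3,Inferoposterolateral myocardial infarction
INJAL,3,Subendocardial injury in anterolateral leads
IPMI,3,Inferoposterior myocardial infarction
PMI,3,Posterior myocardial infarction
3AVB,3,Third degree AV block
ANEUR,3,ST-T changes compatible with ventricular aneurysm
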