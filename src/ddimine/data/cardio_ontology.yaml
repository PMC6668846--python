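# Main and supporting MedDRA preferred terms for the five cardiovascular
# adverse drug effects covered by the shipped models.
ventricular tachycardia:
  main:
    - Torsade de Pointes
    - Ventricular Tachycardia
  supporting:
    - Electrocardiogram QT Prolonged
    - Electrocardiogram QT Corrected Interval Prolonged
    - Ventricular Arrhythmia
myocardial infarction:
  main:
    - Acute Myocardial Infarction
    - Acute Coronary Syndrome
    - Myocardial Infarction
  supporting:
    - Angina Pectoris
    - Angina Unstable
    - Arteriosclerosis Coronary Artery
    - Arteriospasm Coronary
    - Coronary Artery Disease
    - Coronary Artery Occlusion
    - Coronary Artery Stenosis
    - Coronary Artery Thrombosis
    - Myocardial Ischemia
arterial hypertension:
  main:
    - Hypertension
    - Hypertensive Crisis
  supporting:
    - Blood Pressure Increased
    - Blood Pressure Systolic Increased
    - Blood Pressure Diastolic Increased
ischemic stroke:
  main:
    - Cerebrovascular Accident
    - Cerebral Infarction
    - Ischemic Stroke
  supporting:
    - Cerebral Ischemia
    - Transient Ischemic Attack
cardiac failure:
  main:
    - Cardiac Failure Acute
    - Cardiac Failure Congestive
    - Cardiac Failure
    - Cardiogenic Shock
    - Cardiopulmonary Failure
    - Left Ventricular Failure
    - Right Ventricular Failure
  supporting: []
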