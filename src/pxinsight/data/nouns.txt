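admission
advice
aftercare
afternoon
air
anaesthesia
answer
appointment
area
arm
attention
bandage
bathroom
bed
bell
blanket
blood
breakfast
building
button
care
chair
check
clinic
coffee
comfort
communication
complaint
consultant
contact
corridor
curtain
day
daytime
department
diagnosis
dinner
discharge
disease
doctor
door
dose
drink
emergency
entrance
evening
examination
experience
explanation
family
floor
food
form
friendliness
guidance
hallway
hand
heating
help
home
hour
hygiene
illness
information
infusion
injection
instruction
kindness
kitchen
leaflet
letter
light
lunch
machine
mattress
meal
medication
medicine
midwife
minute
mistake
monitor
morning
night
noise
number
nurse
nursing
operation
pain
paperwork
parking
patience
patient
pharmacy
phone
physician
physiotherapist
pillow
plan
planning
porter
privacy
procedure
process
question
queue
reception
receptionist
recovery
rehabilitation
respect
rest
result
room
round
schedule
scan
screen
service
shift
shower
sleep
snack
specialist
staff
stay
stretcher
supper
surgeon
surgery
surroundings
symptom
team
telephone
television
temperature
test
therapist
therapy
time
toilet
towel
transfer
transport
treatment
trolley
visit
visitor
voice
ward
water
weekend
wheelchair
window
wound
xray
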