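# Default CRC-DQI item bank: the 10 retained knowledge items with their
# keyed answers, the 8 retained goals-and-concerns (importance 0-10), the
# 7 goals entering the preference model, and a 5-item brief subset.
#
# The brief subset shipped here is a convention (the first five knowledge
# items); the published short form was never itemized.  Every report that
# uses it says so.
knowledge_items:
  - item_id: K01
    prompt: >-
      At what age do doctors usually recommend people start getting regular
      tests for colon cancer?
    options: ["40", "45", "50", "60", "Not sure"]
    correct_option: "50"
  - item_id: K02
    prompt: >-
      Out of every 100 people about how many will get colon cancer some time
      in their lives?
    options: ["1", "6", "25", "50", "Not sure"]
    correct_option: "6"
  - item_id: K03
    prompt: >-
      Does having a colon cancer test result that is not normal always mean
      that a person has colon cancer?
    options: ["Yes", "No", "Not sure"]
    correct_option: "No"
  - item_id: K04
    prompt: >-
      How often do serious problems, such as serious bleeding or a tear in
      the colon, happen as a result of a colonoscopy?
    options: ["Never", "Rarely", "Often", "Almost always", "Not sure"]
    correct_option: "Rarely"
  - item_id: K05
    prompt: >-
      For a person with an average risk for colon cancer, which test do
      doctors recommend be done every year?
    options: ["Stool blood test", "Colonoscopy", "Sigmoidoscopy", "Barium enema", "Not sure"]
    correct_option: "Stool blood test"
  - item_id: K06
    prompt: >-
      For a person with an average risk for colon cancer, which test do
      doctors recommend be done every 10 years?
    options: ["Stool blood test", "Colonoscopy", "Sigmoidoscopy", "Barium enema", "Not sure"]
    correct_option: "Colonoscopy"
  - item_id: K07
    prompt: >-
      How does regular testing for colon cancer change the chances that a
      person will die from colon cancer?
    options: ["Increases chance", "Decreases chance", "Does not change chance", "Not sure"]
    correct_option: "Decreases chance"
  - item_id: K08
    prompt: Which colon cancer test is least likely to miss a cancer?
    options: ["Stool blood test", "Colonoscopy", "Sigmoidoscopy", "Barium enema", "Not sure"]
    correct_option: "Colonoscopy"
  - item_id: K09
    prompt: >-
      If the results of a colon cancer test are normal, is it possible that a
      person could still have colon cancer?
    options: ["Yes", "No", "Not sure"]
    correct_option: "Yes"
  - item_id: K10
    prompt: Out of every 100 people about how many will die of colon cancer?
    options: ["1", "3", "10", "30", "Not sure"]
    correct_option: "3"

goal_items:
  - goal_id: G_KNOW
    prompt: To know whether or not you have colon cancer
  - goal_id: G_TUBE
    prompt: To avoid a test where a tube is put into your rectum to look at the colon
  - goal_id: G_HARM
    prompt: To avoid a test that can cause bleeding or a tear in the colon
  - goal_id: G_EARLY
    prompt: To try to find colon cancer or polyps early
  - goal_id: G_YEARLY
    prompt: To choose a test that does not need to be done every year
  - goal_id: G_COST
    prompt: To choose a test that doesn't cost you a lot of money
  - goal_id: G_PAIN
    prompt: To avoid a test that may be painful
  - goal_id: G_SLEEPY
    prompt: To choose a test where you take medicine before the test that makes you sleepy

# Covariates of the goal -> test-choice preference model (G_SLEEPY is a
# retained goal but not a model covariate).
model_goals: [G_KNOW, G_TUBE, G_HARM, G_EARLY, G_YEARLY, G_COST, G_PAIN]

# Placeholder convention: first five knowledge items.
brief_subset: [K01, K02, K03, K04, K05]
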